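"""Seeded generators for every input the pipeline consumes, with ground
truth for parameter-recovery tests.

Each generator draws from its own named pseudo-random stream derived from
the single ``SimConfig.seed``, so adding a generator never perturbs the
output of another, and the same seed always yields byte-identical output.

The defaults emulate the statistical shape of the Woesearchaeota MAG
dataset: ~150 ingroup genomes in 10 deep, well-supported subgroups plus 2
ungrouped leaves, rooted by a 30-genome outgroup; a 148-marker archaeal set
of which 5 markers are absent lineage-wide; 4562 gene families over 47
quality-gated genomes; 2320 reconciled families with a 0.3 reporting
threshold; and trimeric-dominated [FeFe]-hydrogenase loci with conserved
P1/P2/P3 motifs.

Planted subgroups are built on a unit-depth ultrametric tree, where RED
equals node depth exactly: a clade's crown is placed at depth = its RED
target, its stem spans from the spine attachment point, and all spine
(backbone) nodes sit at depth <= 0.3 so they can never pass the 0.4 RED
gate. Reconciliation frequencies use truncation-separated noise so that
thresholding at the generator's tau reproduces the planted discrete events
exactly rather than probabilistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .delineate import UNGROUPED, SubgroupAssignment
from .genomeqc import GenomeQuality  # noqa: F401  (re-exported for harnesses)
from .hydrogenase import Gene, OperonRecord
from .reconcile import SIMPLE_TSV_COLUMNS, EventSummary, ReconciliationTable

__all__ = [
    "PlantedClade",
    "SimConfig",
    "sim_tree_with_clades",
    "sim_marker_matrix",
    "sim_family_matrix",
    "sim_reconciliation",
    "sim_operons_and_alignment",
]

_STREAMS = {"tree": 1, "markers": 2, "families": 3, "reconciliation": 4, "operons": 5,
            "annotations": 6}

COG_LETTERS = list("CEFGHIJKLMNOPQTUV")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class PlantedClade:
    size: int
    stem_length: float   # on the unit-depth ultrametric scale
    red_target: float    # crown depth == RED of the clade MRCA
    ufboot: float = 100.0
    shalrt: float = 100.0

    def __post_init__(self):
        if self.size < 2:
            raise ValueError("planted clade needs >= 2 leaves")
        attach = self.red_target - self.stem_length
        if not (0.0 <= attach <= 0.3):
            raise ValueError(
                "red_target - stem_length must lie in [0, 0.3] so backbone "
                f"nodes stay below the RED gate (got {attach:.3f})"
            )
        if self.red_target > 0.9:
            raise ValueError("red_target must be <= 0.9 to leave room for the crown")


def _default_clades(rng: np.random.Generator, k: int, total: int) -> list[PlantedClade]:
    if total < 4 * k:
        raise ValueError(f"n_grouped_leaves must be >= 4 * n_clades (got {total} for {k} clades)")
    sizes = np.full(k, 4)
    extra = rng.multinomial(total - 4 * k, np.ones(k) / k)
    sizes = sizes + extra
    clades = []
    for s in sizes:
        attach = rng.uniform(0.02, 0.25)
        stem = rng.uniform(0.45, 0.6)
        clades.append(PlantedClade(size=int(s), stem_length=stem, red_target=attach + stem))
    return clades


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    # -- tree --
    n_clades: int = 10
    n_grouped_leaves: int = 150
    planted_clades: tuple[PlantedClade, ...] | None = None
    n_outliers: int = 2
    n_outgroup: int = 30
    outlier_supports: tuple[float, float] = (90.0, 70.0)
    # -- markers --
    n_genomes: int = 152
    n_markers: int = 148
    n_absent_markers: int = 5
    completeness_range: tuple[float, float] = (0.5, 0.98)
    contamination_range: tuple[float, float] = (0.0, 0.10)
    # -- gene families --
    n_families: int = 4562
    n_planted_per_subgroup: int = 5
    p_in: float = 0.8
    p_out: float = 0.1
    n_core: int = 109            # high-occupancy single-copy orthologs
    core_presence: float = 0.95
    background_presence: float = 0.04  # mean of the per-family exponential
    multicopy_prob: float = 0.03
    cog_na_mass: float = 0.4
    # -- reconciliation --
    rec_n_families: int = 2320
    event_rate: float = 0.02
    copy_rate: float = 0.2
    freq_noise_sd: float = 0.1
    tau: float = 0.3
    nonevent_noise_prob: float = 0.1
    # -- operons / motifs --
    n_operons: int = 20
    operon_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)  # A3, untyped, not_fefe
    motif_consensus: tuple[tuple[str, str], ...] = (
        ("P1", "TSCCPAW"),
        ("P2", "MPCTAKKSE"),
        ("P3", "ERGCIGGC"),
    )
    n_motif_seqs: int = 30
    substitution_rate: float = 0.1
    preserve_catalytic_cys: bool = True  # purifying selection on metal-binding sites


# ---------------------------------------------------------------------------
# trees


def _newick(node) -> str:
    if node["children"]:
        inner = ",".join(_newick(c) for c in node["children"])
        label = ""
        if node.get("ufboot") is not None:
            label = f"{node['shalrt']:g}/{node['ufboot']:g}"  # SH-aLRT first
        return f"({inner}){label}:{node['length']:.8f}"
    return f"{node['name']}:{node['length']:.8f}"


def _leaf(name: str, depth: float, parent_depth: float) -> dict:
    return {"name": name, "children": [], "length": depth - parent_depth}


def _rand_crown(
    rng: np.random.Generator,
    names: Sequence[str],
    depth: float,
    parent_depth: float,
    ufboot: float | None = 100.0,
    shalrt: float | None = 100.0,
) -> dict:
    """Random ultrametric subtree: crown at ``depth``, leaves at depth 1."""
    if len(names) == 1:
        return _leaf(names[0], 1.0, parent_depth)
    node = {"children": [], "length": depth - parent_depth, "ufboot": ufboot, "shalrt": shalrt}
    cut = int(rng.integers(1, len(names)))
    for part in (names[:cut], names[cut:]):
        if len(part) == 1:
            node["children"].append(_leaf(part[0], 1.0, depth))
        else:
            child_depth = depth + (0.99 - depth) * float(rng.uniform(0.05, 0.9))
            node["children"].append(
                _rand_crown(rng, part, child_depth, depth, 100.0, 100.0)
            )
    return node


def sim_tree_with_clades(cfg: SimConfig):
    """Random rooted unit-depth ultrametric tree with planted subgroups.

    Returns ``(newick_text, truth, info)`` where ``truth`` maps every
    ingroup leaf to its planted subgroup label (``SG01``...) or UNGROUPED,
    and ``info`` records each clade's leaf set, realized stem length, RED
    target and supports, plus the outgroup leaf names.
    """
    rng = _rng(cfg.seed, "tree")
    clades = list(cfg.planted_clades) if cfg.planted_clades is not None else _default_clades(
        rng, cfg.n_clades, cfg.n_grouped_leaves
    )
    if not clades and cfg.n_outliers == 0:
        raise ValueError("nothing to plant: no clades and no outliers")

    # attachments on the backbone spine, ordered by attachment depth
    attachments = []
    clade_leafsets: list[list[str]] = []
    for i, cl in enumerate(clades):
        names = [f"C{i + 1:02d}_g{j + 1:02d}" for j in range(cl.size)]
        clade_leafsets.append(names)
        attachments.append(("clade", i, cl.red_target - cl.stem_length))
    for j in range(cfg.n_outliers):
        attachments.append(("outlier", j, float(rng.uniform(0.05, 0.25))))
    attachments.sort(key=lambda t: t[2])
    if len(attachments) < 2 and cfg.n_outgroup == 0:
        raise ValueError("need an outgroup or at least two spine attachments")

    # strictly increasing spine depths
    depths = []
    for _, _, a in attachments:
        depths.append(a if not depths else max(a, depths[-1] + 1e-4))

    def build_attachment(kind: str, idx: int, parent_depth: float) -> dict:
        if kind == "outlier":
            return _leaf(f"OUT_{idx + 1:02d}", 1.0, parent_depth)
        cl = clades[idx]
        return _rand_crown(
            rng, clade_leafsets[idx], cl.red_target, parent_depth, cl.ufboot, cl.shalrt
        )

    def spine(pos: int, parent_depth: float) -> dict:
        kind, idx, _ = attachments[pos]
        d = depths[pos]
        node = {"children": [], "length": d - parent_depth, "ufboot": 100.0, "shalrt": 100.0}
        if kind == "outlier":
            node["ufboot"], node["shalrt"] = cfg.outlier_supports
        node["children"].append(build_attachment(kind, idx, d))
        if pos + 1 < len(attachments) - 1:
            node["children"].append(spine(pos + 1, d))
        elif pos + 1 == len(attachments) - 1:
            k2, i2, _ = attachments[pos + 1]
            node["children"].append(build_attachment(k2, i2, d))
        return node

    root = {"children": [], "length": 0.0, "ufboot": None, "shalrt": None}
    outgroup_names = [f"PACE_{j + 1:02d}" for j in range(cfg.n_outgroup)]
    if outgroup_names:
        if len(outgroup_names) == 1:
            root["children"].append(_leaf(outgroup_names[0], 1.0, 0.0))
        else:
            root["children"].append(_rand_crown(rng, outgroup_names, 0.3, 0.0))
    if len(attachments) == 1:
        kind, idx, _ = attachments[0]
        root["children"].append(build_attachment(kind, idx, 0.0))
    else:
        root["children"].append(spine(0, 0.0))
    if len(root["children"]) == 1:
        root = root["children"][0]
        root["length"] = 0.0

    text = _newick(root) + ";"

    truth: dict[str, str] = {}
    passes_default: dict[str, bool] = {}
    clade_info = {}
    for i, cl in enumerate(clades):
        label = f"SG{i + 1:02d}"
        slot = next(p for p, (k, idx, _) in enumerate(attachments) if k == "clade" and idx == i)
        spine_depth = depths[min(slot, len(depths) - 2)] if len(depths) > 1 else 0.0
        realized_stem = cl.red_target - spine_depth
        for name in clade_leafsets[i]:
            truth[name] = label
        passes_default[label] = (
            cl.ufboot >= 95.0
            and cl.shalrt >= 80.0
            and cl.red_target > 0.4
            and realized_stem > 0.4
        )
        clade_info[label] = {
            "leaves": frozenset(clade_leafsets[i]),
            "red": cl.red_target,
            "stem": realized_stem,
            "ufboot": cl.ufboot,
            "shalrt": cl.shalrt,
        }
    for j in range(cfg.n_outliers):
        truth[f"OUT_{j + 1:02d}"] = UNGROUPED
    info = {
        "clades": clade_info,
        "passes_default": passes_default,
        "outgroup": outgroup_names,
    }
    return text, truth, info


def truth_assignment(truth: dict[str, str]) -> SubgroupAssignment:
    """Wrap a generator truth map as a SubgroupAssignment (labels only)."""
    return SubgroupAssignment(leaf_to_label=dict(truth), subgroups=[])


# ---------------------------------------------------------------------------
# markers


def sim_marker_matrix(cfg: SimConfig):
    """Genome x marker copy counts with known per-genome truth.

    Presence of each informative marker is Bernoulli at the genome's true
    completeness; a present marker gains one extra copy at the genome's
    duplication (contamination) rate. The last ``n_absent_markers`` columns
    are zero lineage-wide, emulating markers the clade lost. Draws use
    common random numbers, so raising only the contamination range can
    never remove a duplication (estimates are monotone in the rate).
    """
    rng = _rng(cfg.seed, "markers")
    G, M, A = cfg.n_genomes, cfg.n_markers, cfg.n_absent_markers
    if A >= M:
        raise ValueError("n_absent_markers must be < n_markers")
    c = cfg.completeness_range[0] + (
        cfg.completeness_range[1] - cfg.completeness_range[0]
    ) * rng.random(G)
    x = cfg.contamination_range[0] + (
        cfg.contamination_range[1] - cfg.contamination_range[0]
    ) * rng.random(G)
    u_pres = rng.random((G, M - A))
    u_dup = rng.random((G, M - A))
    presence = (u_pres < c[:, None]).astype(int)
    extra = ((u_dup < x[:, None]) & (presence > 0)).astype(int)
    counts = np.concatenate([presence + extra, np.zeros((G, A), dtype=int)], axis=1)

    genomes = [f"G{i + 1:03d}" for i in range(G)]
    markers = [f"MK{j + 1:04d}" for j in range(M)]
    m = pd.DataFrame(counts, index=genomes, columns=markers)
    truth = pd.DataFrame(
        {"completeness": 100.0 * c, "contamination_rate": x}, index=genomes
    )
    return m, truth


# ---------------------------------------------------------------------------
# gene families


def sim_family_matrix(cfg: SimConfig, assignment: SubgroupAssignment):
    """Clade-enriched presence/absence counts plus COG annotations.

    Family classes, in column order: (1) per-subgroup planted families,
    present at ``p_in`` inside their subgroup and ``p_out`` elsewhere;
    (2) ``n_core`` high-occupancy strictly single-copy orthologs at
    ``core_presence`` (emulating the concatenation candidates); (3)
    background families whose per-family presence probability is drawn from
    an exponential with mean ``background_presence``, giving the skewed,
    rare-family-heavy size distribution of real pangenomes. Non-core
    present genes carry a second copy with probability ``multicopy_prob``.
    Returns ``(FamilyMatrix, annotations, truth)`` with truth mapping each
    planted family to its subgroup.
    """
    rng = _rng(cfg.seed, "families")
    genomes = sorted(assignment.leaf_to_label)
    labels = sorted({l for l in assignment.leaf_to_label.values() if l != UNGROUPED})
    n_planted = cfg.n_planted_per_subgroup * len(labels)
    if n_planted + cfg.n_core > cfg.n_families:
        raise ValueError("n_families too small for planted plus core families")
    fams = [f"FAM{k + 1:05d}" for k in range(cfg.n_families)]

    prob = np.empty((len(genomes), cfg.n_families))
    truth: dict[str, str] = {}
    col = 0
    for lab in labels:
        members = np.array([assignment.leaf_to_label[g] == lab for g in genomes])
        for _ in range(cfg.n_planted_per_subgroup):
            prob[:, col] = np.where(members, cfg.p_in, cfg.p_out)
            truth[fams[col]] = lab
            col += 1
    core_cols = slice(col, col + cfg.n_core)
    prob[:, core_cols] = cfg.core_presence
    n_bg = cfg.n_families - col - cfg.n_core
    bg_p = np.minimum(rng.exponential(cfg.background_presence, n_bg), 0.95)
    prob[:, col + cfg.n_core:] = bg_p[None, :]
    present = (rng.random(prob.shape) < prob).astype(int)
    extra = ((rng.random(prob.shape) < cfg.multicopy_prob) & (present > 0)).astype(int)
    extra[:, core_cols] = 0  # core orthologs stay strictly single-copy
    fm = pd.DataFrame(present + extra, index=genomes, columns=fams)

    na_mass = cfg.cog_na_mass
    cat_p = [na_mass] + [(1 - na_mass) / len(COG_LETTERS)] * len(COG_LETTERS)
    cats = rng.choice(["NA"] + COG_LETTERS, size=cfg.n_families, p=cat_p)
    annotations = pd.Series(cats, index=fams, name="cog")
    return fm, annotations, truth


def sim_cog_annotations(cfg: SimConfig, family_ids: Sequence[str]) -> pd.Series:
    """COG category (or NA) per family, from the shared categorical model
    but on its own stream, so it can annotate any family universe (e.g. the
    reconciled families) without perturbing other generators."""
    rng = _rng(cfg.seed, "annotations")
    na_mass = cfg.cog_na_mass
    cat_p = [na_mass] + [(1 - na_mass) / len(COG_LETTERS)] * len(COG_LETTERS)
    cats = rng.choice(["NA"] + COG_LETTERS, size=len(family_ids), p=cat_p)
    return pd.Series(cats, index=list(family_ids), name="cog")


# ---------------------------------------------------------------------------
# reconciliation


def sim_reconciliation(cfg: SimConfig, branches: Iterable[str]):
    """Event-frequency table with exactly recoverable planted events.

    True discrete events are Bernoulli draws per (family, branch, type).
    Reported frequencies are separated by construction: a true event gets
    1 - |N(0, sd)| clipped into (tau, 1]; a non-event gets |N(0, sd)|
    clipped into [0, tau) (and is usually exactly 0), so thresholding
    strictly at tau reproduces the planted counts exactly.
    """
    rng = _rng(cfg.seed, "reconciliation")
    branches = list(branches)
    B, F = len(branches), cfg.rec_n_families
    if B == 0:
        raise ValueError("no branches given")
    fams = [f"RF{k + 1:05d}" for k in range(F)]
    margin = min(0.05, cfg.tau / 2) if cfg.tau > 0 else 0.0
    lo, hi = cfg.tau - margin, cfg.tau + margin

    def freq_for(true_events: np.ndarray) -> np.ndarray:
        noise = np.abs(rng.normal(0.0, cfg.freq_noise_sd, true_events.shape))
        on = np.clip(1.0 - noise, hi if hi > 0 else 1e-6, 1.0)
        off_active = rng.random(true_events.shape) < cfg.nonevent_noise_prob
        off = np.where(off_active, np.clip(noise, 0.0, max(lo, 0.0)), 0.0)
        return np.where(true_events, on, off)

    true_ev = rng.random((F, B, 4)) < cfg.event_rate  # D, T, L, O
    true_cp = rng.random((F, B)) < cfg.copy_rate
    freqs = freq_for(true_ev)
    copies = freq_for(true_cp)

    nz = true_ev.any(axis=2) | (freqs > 0).any(axis=2) | (copies > 0)
    fi, bi = np.nonzero(nz)
    df = pd.DataFrame(
        {
            "family": [fams[i] for i in fi],
            "branch": [branches[j] for j in bi],
            "D": freqs[fi, bi, 0],
            "T": freqs[fi, bi, 1],
            "L": freqs[fi, bi, 2],
            "O": freqs[fi, bi, 3],
            "copies": copies[fi, bi],
        }
    )
    rt = ReconciliationTable(freq=df[SIMPLE_TSV_COLUMNS])

    ev_counts = pd.DataFrame(
        true_ev.sum(axis=0), index=branches, columns=["n_D", "n_T", "n_L", "n_O"]
    )
    ev_counts["n_gain"] = ev_counts["n_D"] + ev_counts["n_T"] + ev_counts["n_O"]
    ev_counts = ev_counts.sort_index()
    ev_counts.index.name = "branch"
    cp_counts = pd.Series(true_cp.sum(axis=0), index=branches, name="n_copies").sort_index()
    cp_counts.index.name = "branch"
    gain_mask = true_ev[:, :, [0, 1, 3]].any(axis=2)
    gained = {
        b: sorted(fams[i] for i in np.nonzero(gain_mask[:, j])[0])
        for j, b in enumerate(branches)
    }
    truth = EventSummary(events=ev_counts, copies=cp_counts, gained=gained, tau=cfg.tau)
    return rt, truth


# ---------------------------------------------------------------------------
# operons and motif alignments


def _operon_genes(rng: np.random.Generator, label: str, contig: str) -> list[Gene]:
    strand = "+" if rng.random() < 0.5 else "-"
    layouts = {
        "A3_trimeric": [
            ["nuoE_like", "nuoF_like", "H_cluster"],
            ["H_cluster", "nuoF_like", "nuoE_like"],
            ["nuoF_like", "H_cluster", "nuoE_like"],
        ],
        "A_untyped": [["other", "H_cluster", "other"], ["H_cluster"], ["other", "H_cluster"]],
        "not_fefe": [["other", "other"], ["other", "other", "other"]],
    }
    domains = layouts[label][int(rng.integers(len(layouts[label])))]
    if label == "A_untyped" and "nuoF_like" not in domains and rng.random() < 0.5:
        # partner present but on the opposite strand: context broken
        domains = domains + ["nuoF_like"]
        flip_last = True
    else:
        flip_last = False
    genes = []
    pos = int(rng.integers(1, 5000))
    for k, dom in enumerate(domains):
        length = int(rng.integers(300, 1800))
        st = strand
        if flip_last and k == len(domains) - 1:
            st = "-" if strand == "+" else "+"
        genes.append(
            Gene(
                gene_id=f"{contig}_g{k + 1}",
                strand=st,
                start=pos,
                end=pos + length,
                domains={dom},
            )
        )
        pos += length + int(rng.integers(20, 200))
    return genes


def sim_operons_and_alignment(cfg: SimConfig):
    """Operon records with known class labels plus a motif alignment.

    Returns ``(operons, op_labels, aln, refs, windows, consensus, cys_cols)``.
    The alignment has ``n_motif_seqs`` query sequences mutated from a
    planted consensus at ``substitution_rate`` per site, and three
    reference sequences equal to the consensus; windows are 1-based
    inclusive column ranges around each motif, and ``cys_cols`` lists the
    consensus cysteine columns inside them.
    """
    rng = _rng(cfg.seed, "operons")
    mix = np.asarray(cfg.operon_mix, dtype=float)
    if mix.sum() <= 0:
        raise ValueError("operon_mix must have positive mass")
    mix = mix / mix.sum()
    classes = ("A3_trimeric", "A_untyped", "not_fefe")
    operons, op_labels = [], {}
    for i in range(cfg.n_operons):
        label = classes[int(rng.choice(3, p=mix))]
        contig = f"ctg{i + 1:03d}"
        operons.append(OperonRecord(contig=contig, genes=_operon_genes(rng, label, contig)))
        op_labels[contig] = label

    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    motifs = dict(cfg.motif_consensus)
    spacer = 12
    consensus_parts, windows, col = [], {}, 1
    for name, motif in motifs.items():
        gap_block = "".join(aa[rng.integers(0, 20, spacer)])
        consensus_parts.append(gap_block)
        col += spacer
        windows[name] = (col, col + len(motif) - 1)
        consensus_parts.append(motif)
        col += len(motif)
    consensus_parts.append("".join(aa[rng.integers(0, 20, spacer)]))
    consensus = "".join(consensus_parts)

    refs = {
        "ref_Thermotoga_synthetic": consensus,
        "ref_Desulfovibrio_synthetic": consensus,
        "ref_Clostridium_synthetic": consensus,
    }
    cys_cols = [
        c
        for name, (lo, hi) in windows.items()
        for c in range(lo, hi + 1)
        if consensus[c - 1] == "C"
    ]
    frozen = set(c - 1 for c in cys_cols) if cfg.preserve_catalytic_cys else set()
    aln = {}
    cons_arr = np.array(list(consensus))
    for i in range(cfg.n_motif_seqs):
        seq = cons_arr.copy()
        hits = np.nonzero(rng.random(len(seq)) < cfg.substitution_rate)[0]
        for h in hits:
            if h in frozen:
                continue
            choices = aa[aa != seq[h]]
            seq[h] = choices[int(rng.integers(len(choices)))]
        aln[f"woese_{i + 1:02d}"] = "".join(seq)
    return operons, op_labels, aln, refs, windows, consensus, cys_cols


def scaled(cfg: SimConfig, **overrides) -> SimConfig:
    """Convenience: a copy of the config with fields replaced."""
    return replace(cfg, **overrides)
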