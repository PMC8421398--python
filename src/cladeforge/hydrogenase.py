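"""[FeFe]-hydrogenase operon classification and P1/P2/P3 motif profiling.

Group A3 [FeFe] hydrogenases are trimeric, electron-bifurcating enzymes: a
catalytic H-cluster subunit flanked by nuoF-like and nuoE-like genes. A
locus is called ``A3_trimeric`` when an H-cluster gene has both partners
within a small gene-adjacency window on the same strand; an H-cluster gene
without that context is ``A_untyped``; anything else is ``not_fefe``.

Motif conservation is profiled as per-column amino-acid probabilities
(including the gap character) over reference-anchored alignment windows,
and residues are classed by Kyte-Doolittle hydropathy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

__all__ = [
    "Gene",
    "OperonRecord",
    "MotifProfile",
    "read_operons_tsv",
    "classify_fefe_operon",
    "read_alignment_fasta",
    "extract_motif_profile",
    "compare_to_references",
    "check_catalytic_cysteines",
]

DOMAIN_LABELS = ("H_cluster", "nuoF_like", "nuoE_like", "other")
GAP = "-"
AA_ORDER = list("ACDEFGHIKLMNPQRSTVWY") + [GAP]


@dataclass
class Gene:
    gene_id: str
    strand: str  # "+" or "-"
    start: int   # 1-based inclusive
    end: int
    domains: set = field(default_factory=set)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"gene {self.gene_id!r}: invalid coordinates {self.start}..{self.end}")


@dataclass
class OperonRecord:
    contig: str
    genes: list  # sorted by start

    def __post_init__(self):
        self.genes = sorted(self.genes, key=lambda g: g.start)


def read_operons_tsv(path) -> list[OperonRecord]:
    """TSV columns: contig, gene_id, start, end, strand, domains
    (semicolon-separated labels)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "gene_id": str})
    need = {"contig", "gene_id", "start", "end", "strand", "domains"}
    if not need <= set(df.columns):
        raise ValueError(f"operon table missing columns {sorted(need - set(df.columns))}")
    records = []
    for contig, grp in df.groupby("contig", sort=True):
        genes = [
            Gene(
                gene_id=row.gene_id,
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                domains=set(str(row.domains).split(";")) - {"", "nan"},
            )
            for row in grp.itertuples()
        ]
        records.append(OperonRecord(contig=contig, genes=genes))
    return records


def classify_fefe_operon(
    op: OperonRecord,
    max_gene_gap: int = 1,
    same_strand: bool = True,
) -> str:
    """Classify an operon as A3_trimeric, A_untyped, or not_fefe.

    A3_trimeric requires an H-cluster gene with a nuoF-like and a nuoE-like
    gene each within ``max_gene_gap`` intervening genes (and on the same
    strand when ``same_strand``). The call is invariant under reversing the
    gene order together with flipping strands.
    """
    genes = op.genes
    h_idx = [i for i, g in enumerate(genes) if "H_cluster" in g.domains]
    if not h_idx:
        return "not_fefe"
    for i in h_idx:
        h = genes[i]
        near = [
            g
            for j, g in enumerate(genes)
            if j != i
            and abs(j - i) - 1 <= max_gene_gap
            and (not same_strand or g.strand == h.strand)
        ]
        has_f = any("nuoF_like" in g.domains for g in near)
        has_e = any("nuoE_like" in g.domains for g in near)
        if has_f and has_e:
            return "A3_trimeric"
    return "A_untyped"


def read_alignment_fasta(path) -> dict[str, str]:
    aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not aln:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment in {path}: lengths {sorted(lengths)}")
    return aln


@dataclass
class MotifProfile:
    """Per-column amino-acid probabilities over an alignment window.

    ``probs`` rows are 1-based alignment columns; columns are the 20 amino
    acids plus the gap character, each row summing to 1.
    """

    name: str
    columns: list[int]
    probs: pd.DataFrame
    hydrophobicity: dict[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))

    def modal_residues(self) -> str:
        return "".join(self.probs.loc[c].idxmax() for c in self.columns)


def _check_windows(aln: Mapping[str, str], windows: Mapping[str, tuple[int, int]]):
    ncol = len(next(iter(aln.values())))
    for name, (lo, hi) in windows.items():
        if not (1 <= lo <= hi <= ncol):
            raise ValueError(f"window {name!r} = ({lo}, {hi}) outside alignment of {ncol} columns")


def extract_motif_profile(
    aln: Mapping[str, str],
    motif_windows: Mapping[str, tuple[int, int]],
) -> dict[str, MotifProfile]:
    """Empirical per-column residue frequencies for each motif window
    (1-based inclusive column ranges)."""
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    _check_windows(aln, motif_windows)
    n = len(aln)
    out = {}
    for name, (lo, hi) in motif_windows.items():
        cols = list(range(lo, hi + 1))
        probs = pd.DataFrame(0.0, index=cols, columns=AA_ORDER)
        for seq in aln.values():
            for c in cols:
                ch = seq[c - 1]
                ch = ch if ch in probs.columns else GAP
                probs.loc[c, ch] += 1.0
        probs /= n
        out[name] = MotifProfile(name=name, columns=cols, probs=probs)
    return out


def _hydro_class(residue: str, thresholds: tuple[float, float]) -> str | None:
    if residue not in KYTE_DOOLITTLE:
        return None
    hi, lo = thresholds
    v = KYTE_DOOLITTLE[residue]
    if v > hi:
        return "hydrophobic"
    if v < lo:
        return "hydrophilic"
    return "neutral"


def compare_to_references(
    seqs: Mapping[str, str],
    refs: Mapping[str, str],
    windows: Mapping[str, tuple[int, int]],
    kd_thresholds: tuple[float, float] = (0.5, -0.5),
) -> pd.DataFrame:
    """Per-site conservation against reference sequences.

    A site is conserved when the query residue is identical to the residue
    of every reference at that column. Residues are classed by the
    Kyte-Doolittle hydropathy index (> +0.5 hydrophobic, < -0.5 hydrophilic,
    neutral between; thresholds configurable); gaps have class NA (None).
    """
    both = {**seqs, **refs}
    lengths = {len(s) for s in both.values()}
    if len(lengths) != 1:
        raise ValueError("query and reference sequences must share alignment coordinates")
    _check_windows(both, windows)
    rows = []
    for name, (lo, hi) in windows.items():
        for c in range(lo, hi + 1):
            ref_res = {s[c - 1] for s in refs.values()}
            for sid in sorted(seqs):
                res = seqs[sid][c - 1]
                conserved = len(ref_res) == 1 and res in ref_res and res != GAP
                rows.append(
                    {
                        "motif": name,
                        "seq_id": sid,
                        "position": c,
                        "residue": res,
                        "conserved": conserved,
                        "hydrophobicity_class": _hydro_class(res, kd_thresholds),
                    }
                )
    return pd.DataFrame(rows)


def check_catalytic_cysteines(
    seqs: Mapping[str, str],
    cys_columns: Iterable[int],
) -> dict[str, bool]:
    """True per sequence iff the residue is C at every listed 1-based column
    (metal-binding cysteines of the H-cluster)."""
    cols = list(cys_columns)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment")
    ncol = lengths.pop()
    if any(c < 1 or c > ncol for c in cols):
        raise ValueError("cysteine column outside alignment")
    return {sid: all(seq[c - 1] == "C" for c in cols) for sid, seq in seqs.items()}
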