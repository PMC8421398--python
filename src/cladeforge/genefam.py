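"""Gene-family occupancy filters, per-subgroup occurrence profiles, medoid
selection, and COG-category composition.

The family matrix is a DataFrame of copy counts (genomes x families);
annotations are a family-indexed Series of COG category letters, KO ids, or
"NA" for unannotated families.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .delineate import UNGROUPED, SubgroupAssignment

__all__ = [
    "NA_CATEGORY",
    "filter_families_min_size",
    "filter_single_copy_orthologs",
    "occurrence_by_subgroup",
    "select_medoid",
    "pairwise_distance_matrix",
    "category_composition",
]

NA_CATEGORY = "NA"
# the 20 standard amino acids accepted by the medoid aligner
_AA = set("ACDEFGHIKLMNPQRSTVWY")


def filter_families_min_size(fm: pd.DataFrame, min_seqs: int = 4) -> pd.DataFrame:
    """Drop families with fewer than ``min_seqs`` total sequences.

    The study removed families with <4 sequences before tree inference and
    reconciliation; the same default applies here.
    """
    if min_seqs < 1:
        raise ValueError("min_seqs must be >= 1")
    keep = fm.columns[fm.sum(axis=0) >= min_seqs]
    if len(keep) == 0:
        warnings.warn("every family falls below the size threshold", stacklevel=2)
    return fm[keep]


def filter_single_copy_orthologs(
    fm: pd.DataFrame,
    occupancy: float = 0.85,
    allow_multicopy_in: Iterable[str] = (),
) -> list[str]:
    """Families present in >= ceil(occupancy * n_genomes) genomes and
    single-copy in every genome outside ``allow_multicopy_in``."""
    if not (0.0 < occupancy <= 1.0):
        raise ValueError("occupancy must lie in (0, 1]")
    allow = set(allow_multicopy_in)
    need = math.ceil(occupancy * fm.shape[0])
    strict = fm.loc[[g for g in fm.index if g not in allow]]
    out = []
    for fam in fm.columns:
        if int((fm[fam] >= 1).sum()) >= need and (strict[fam] <= 1).all():
            out.append(fam)
    return out


def occurrence_by_subgroup(
    fm: pd.DataFrame,
    assignment: SubgroupAssignment,
    genes_of_interest: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Percent of genomes in each subgroup carrying each gene family.

    Occurrence is computed from presence/absence (count >= 1) across the
    total number of genomes in each subgroup; UNGROUPED genomes contribute
    to no subgroup column. Returns (occurrence table, subgroup sizes).
    """
    missing = [g for g in fm.index if g not in assignment.leaf_to_label]
    if missing:
        raise ValueError(f"genomes without a subgroup assignment: {missing}")
    genes = list(genes_of_interest) if genes_of_interest is not None else list(fm.columns)
    labels = sorted({l for l in assignment.leaf_to_label.values() if l != UNGROUPED})
    sizes = {}
    occ = pd.DataFrame(index=genes, columns=labels, dtype=float)
    for lab in labels:
        members = [g for g in fm.index if assignment.leaf_to_label[g] == lab]
        sizes[lab] = len(members)
        sub = fm.loc[members, genes]
        occ[lab] = 100.0 * (sub >= 1).sum(axis=0) / len(members)
    occ.index.name = "family"
    return occ, pd.Series(sizes, name="n_genomes")


def _check_protein(seq_id: str, seq: str) -> None:
    bad = set(seq.upper()) - _AA
    if bad:
        raise ValueError(
            f"sequence {seq_id!r} contains non-amino-acid characters: {sorted(bad)}"
        )


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.substitution_matrix = substitution_matrices.load(matrix)
    aln.mode = "global"
    aln.open_gap_score = gap_open
    aln.extend_gap_score = gap_extend
    return aln


def pairwise_distance_matrix(
    seqs: Mapping[str, str],
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> pd.DataFrame:
    """Normalized global-alignment distances d(a,b) = 1 - S(a,b)/max(S(a,a), S(b,b))."""
    ids = sorted(seqs)
    for sid in ids:
        if not seqs[sid]:
            raise ValueError(f"empty sequence {sid!r}")
        _check_protein(sid, seqs[sid])
    aln = _aligner(matrix, gap_open, gap_extend)
    self_score = {sid: aln.score(seqs[sid], seqs[sid]) for sid in ids}
    d = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            s = aln.score(seqs[a], seqs[b])
            dist = 1.0 - s / max(self_score[a], self_score[b])
            d.loc[a, b] = d.loc[b, a] = dist
    return d


def select_medoid(
    seqs: Mapping[str, str],
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> str:
    """The sequence with the shortest summed genetic distance to all others.

    Distances come from global BLOSUM62 alignment scores normalized by the
    larger self-score; ties break lexicographically by id. The gap penalties
    and the normalization are configurable: any monotone transform of the
    scores preserves the argmin when self-scores are equal.
    """
    if not seqs:
        raise ValueError("no sequences given")
    if len(seqs) == 1:
        (only,) = seqs
        _check_protein(only, seqs[only])
        return only
    d = pairwise_distance_matrix(seqs, matrix, gap_open, gap_extend)
    sums = d.sum(axis=1)
    best = sums.min()
    return min(sid for sid in sums.index if sums[sid] == best)


def category_composition(
    family_ids: Iterable[str],
    annotations: Mapping[str, str],
) -> pd.Series:
    """Fraction of families per COG category over the given set.

    Families missing from ``annotations`` (or annotated "NA") count toward
    the NA mass; a multi-letter category like "EH" is split fractionally so
    the composition always sums to 1.
    """
    fams = list(family_ids)
    if not fams:
        return pd.Series(dtype=float)
    weights: dict[str, float] = {}
    share = 1.0 / len(fams)
    for fam in fams:
        cat = annotations.get(fam, NA_CATEGORY) if hasattr(annotations, "get") else NA_CATEGORY
        # NaN from a round-trip through pandas counts as unannotated
        if not isinstance(cat, str) or cat == "" or cat == NA_CATEGORY:
            weights[NA_CATEGORY] = weights.get(NA_CATEGORY, 0.0) + share
        else:
            letters = list(cat)
            for letter in letters:
                weights[letter] = weights.get(letter, 0.0) + share / len(letters)
    return pd.Series(weights).sort_index()
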