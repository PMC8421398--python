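"""Marker-set refinement and marker-based genome quality estimation.

The marker matrix is a pandas DataFrame of nonnegative integer copy counts
with genomes as rows and marker accessions as columns. Markers absent from
every genome are uninformative for the lineage and are dropped before
estimation (in the Woesearchaeota study this step reduced the archaeal
CheckM set from 148 to 143 markers).

The quality estimator is deliberately simple and fully specified:
completeness is the percentage of markers present at least once, and
contamination counts extra copies per marker,

    completeness  = 100 * |{i : c_i >= 1}| / M
    contamination = 100 * sum_i max(0, c_i - 1) / M.

This approximates, but is not, CheckM's collocated-marker-set algorithm;
it operates on the flat refined marker list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GenomeQuality",
    "read_marker_matrix",
    "refine_marker_set",
    "estimate_quality",
    "filter_genomes",
]


@dataclass
class GenomeQuality:
    genome: str
    completeness: float  # percent, <= 100
    contamination: float  # percent, >= 0


def read_marker_matrix(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    validate_marker_matrix(m)
    return m


def validate_marker_matrix(m: pd.DataFrame) -> None:
    if (m.values < 0).any():
        raise ValueError("marker counts must be nonnegative")
    if not all(float(x).is_integer() for x in m.values.ravel()):
        raise ValueError("marker counts must be integers")


def refine_marker_set(m: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split markers into (retained, excluded-as-all-absent), order preserved."""
    if m.shape[0] < 1:
        raise ValueError("need at least one genome")
    col_sums = m.sum(axis=0)
    excluded = [c for c in m.columns if col_sums[c] == 0]
    retained = [c for c in m.columns if col_sums[c] > 0]
    if not retained:
        warnings.warn("every marker column is zero; all markers excluded", stacklevel=2)
    return retained, excluded


def estimate_quality(m: pd.DataFrame) -> list[GenomeQuality]:
    if m.shape[1] == 0:
        raise ValueError("no markers in matrix")
    M = m.shape[1]
    out = []
    for genome, row in m.iterrows():
        present = int((row >= 1).sum())
        extra = int(row.clip(lower=1).sum()) - M  # sum of max(0, c-1)
        out.append(
            GenomeQuality(
                genome=str(genome),
                completeness=100.0 * present / M,
                contamination=100.0 * extra / M,
            )
        )
    return out


def quality_frame(q: list[GenomeQuality]) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.genome, g.completeness, g.contamination) for g in q],
        columns=["genome", "completeness", "contamination"],
    )


def filter_genomes(
    q: list[GenomeQuality],
    comp_min: float,
    cont_max: float,
    comp_strict: bool = False,
    cont_strict: bool = False,
) -> list[str]:
    """Genomes passing both quality gates, input order preserved.

    Gate strictness is explicit per gate: the lineage-wide screen uses
    completeness >= 50 and contamination <= 10, while the reconciliation
    subset uses the stricter > 79 / < 5 reading.
    """
    def comp_ok(g):
        return g.completeness > comp_min if comp_strict else g.completeness >= comp_min

    def cont_ok(g):
        return g.contamination < cont_max if cont_strict else g.contamination <= cont_max

    return [g.genome for g in q if comp_ok(g) and cont_ok(g)]
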