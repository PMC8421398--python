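"""Reconciliation event-frequency tables and frequency-thresholded event
accounting.

Gene-tree/species-tree reconciliation (e.g. ALE's undated DTL model)
reports, per gene family and species-tree branch, the expected frequency of
duplications (D), transfers within the sampled genomes (T), losses (L) and
originations (O, arrivals from unsampled lineages or de novo births), plus
expected gene-copy numbers at nodes. Discrete event counts are obtained by
thresholding these frequencies; the study reports events whose frequency is
over 0.3, and "gains" on a branch are D + T + O.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .genefam import category_composition

__all__ = [
    "EVENT_TYPES",
    "ReconciliationTable",
    "EventSummary",
    "parse_reconciliation",
    "threshold_events",
    "summarize_gains",
    "gain_composition",
]

EVENT_TYPES = ("D", "T", "L", "O")
SIMPLE_TSV_COLUMNS = ["family", "branch", "D", "T", "L", "O", "copies"]


@dataclass
class ReconciliationTable:
    """Long-format frequencies: one row per (family, branch) with D/T/L/O
    and copies columns; absent cells are implicitly zero."""

    freq: pd.DataFrame  # columns: family, branch, D, T, L, O, copies

    def __post_init__(self):
        missing = [c for c in SIMPLE_TSV_COLUMNS if c not in self.freq.columns]
        if missing:
            raise ValueError(f"reconciliation table missing columns {missing}")
        vals = self.freq[["D", "T", "L", "O", "copies"]].to_numpy(dtype=float)
        if not (vals >= 0).all() or not pd.notna(vals).all():
            raise ValueError("frequencies must be finite and >= 0")

    @property
    def families(self) -> list[str]:
        return sorted(self.freq["family"].unique())

    @property
    def branches(self) -> list[str]:
        return sorted(self.freq["branch"].unique())


def _parse_simple_tsv(path, branches) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SIMPLE_TSV_COLUMNS:
            raise ValueError(
                f"{path}: line 1: expected header {SIMPLE_TSV_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 fields, got {len(parts)}")
            fam, br = parts[0], parts[1]
            if branches is not None and br not in branches:
                raise ValueError(f"{path}: line {lineno}: unknown branch id {br!r}")
            try:
                nums = [float(x) for x in parts[2:]]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric frequency") from exc
            if any(x < 0 for x in nums):
                raise ValueError(f"{path}: line {lineno}: negative frequency")
            rows.append([fam, br] + nums)
    return pd.DataFrame(rows, columns=SIMPLE_TSV_COLUMNS)


def _parse_ale_uml_file(path, branches) -> list[list]:
    """One uml_rec-style file holds one family; branch rows start with
    S_terminal_branch / S_internal_branch and carry D, T, L, O, copies."""
    fam = os.path.splitext(os.path.basename(path))[0]
    for suffix in (".uml_rec", ".ale"):
        if fam.endswith(suffix):
            fam = fam[: -len(suffix)]
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("S_terminal_branch", "S_internal_branch")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 fields, got {len(parts)}")
            br = parts[1]
            if branches is not None and br not in branches:
                raise ValueError(f"{path}: line {lineno}: unknown branch id {br!r}")
            try:
                d, t, l, o, copies = (float(x) for x in parts[2:])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric frequency") from exc
            if min(d, t, l, o, copies) < 0:
                raise ValueError(f"{path}: line {lineno}: negative frequency")
            rows.append([fam, br, d, t, l, o, copies])
    return rows


def parse_reconciliation(
    path,
    dialect: str = "simple_tsv",
    branches: Iterable[str] | None = None,
) -> ReconciliationTable:
    """Read event frequencies from disk.

    ``simple_tsv``: one file, tab-separated, header
    ``family branch D T L O copies``. ``ale_uml``: a single uml_rec-style
    file (one family) or a directory of them.
    """
    branch_set = set(branches) if branches is not None else None
    if dialect == "simple_tsv":
        df = _parse_simple_tsv(path, branch_set)
    elif dialect == "ale_uml":
        if os.path.isdir(path):
            rows = []
            for name in sorted(os.listdir(path)):
                rows.extend(_parse_ale_uml_file(os.path.join(path, name), branch_set))
        else:
            rows = _parse_ale_uml_file(path, branch_set)
        df = pd.DataFrame(rows, columns=SIMPLE_TSV_COLUMNS)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return ReconciliationTable(freq=df)


@dataclass
class EventSummary:
    """Discrete per-branch event counts after frequency thresholding."""

    events: pd.DataFrame  # index: branch; columns n_D, n_T, n_L, n_O, n_gain
    copies: pd.Series     # index: node (branch id); families with copies > tau
    gained: dict[str, list[str]] = field(default_factory=dict)
    tau: float = 0.3

    def branch(self, b: str) -> pd.Series:
        if b not in self.events.index:
            raise KeyError(f"branch {b!r} not in summary")
        return self.events.loc[b]


def threshold_events(
    rt: ReconciliationTable,
    tau: float = 0.3,
    inclusive: bool = False,
) -> EventSummary:
    """Count one event per (family, branch, type) whose frequency exceeds tau.

    The comparison is strict (frequency > tau) by default, the reading of
    "events with a frequency over 0.3"; ``inclusive=True`` gives >= tau.
    Copy counts at nodes are thresholded the same way. Gains on a branch are
    n_D + n_T + n_O, and the gained family ids are recorded per branch.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    df = rt.freq
    # 1e-12 guard keeps representation noise from flipping the strict
    # comparison for frequencies exactly at tau
    cut = tau - 1e-12 if inclusive else tau + 1e-12
    hit = df[list(EVENT_TYPES)] >= cut if inclusive else df[list(EVENT_TYPES)] > cut
    counts = hit.groupby(df["branch"]).sum().astype(int)
    counts.columns = [f"n_{c}" for c in counts.columns]
    for c in ("n_D", "n_T", "n_L", "n_O"):
        if c not in counts.columns:
            counts[c] = 0
    counts["n_gain"] = counts["n_D"] + counts["n_T"] + counts["n_O"]
    counts = counts[["n_D", "n_T", "n_L", "n_O", "n_gain"]].sort_index()
    counts.index.name = "branch"

    copy_hit = df["copies"] >= cut if inclusive else df["copies"] > cut
    copies = copy_hit.groupby(df["branch"]).sum().astype(int).sort_index()
    copies.name = "n_copies"

    gain_mask = hit[["D", "T", "O"]].any(axis=1)
    gained: dict[str, list[str]] = {b: [] for b in counts.index}
    for _, row in df[gain_mask].iterrows():
        gained[row["branch"]].append(row["family"])
    gained = {b: sorted(set(v)) for b, v in gained.items()}
    return EventSummary(events=counts, copies=copies, gained=gained, tau=tau)


def summarize_gains(es: EventSummary, branch: str) -> dict:
    """Gain counts and their percent shares (nearest percent) on a branch.

    Shares are component / n_gain with gains = D + T + O; when the branch
    has no gains the shares are reported as None (NA).
    """
    row = es.branch(branch)
    n_d, n_t, n_o = int(row["n_D"]), int(row["n_T"]), int(row["n_O"])
    n_gain = n_d + n_t + n_o
    if n_gain == 0:
        shares = {"share_O": None, "share_T": None, "share_D": None}
    else:
        shares = {
            "share_O": round(100.0 * n_o / n_gain),
            "share_T": round(100.0 * n_t / n_gain),
            "share_D": round(100.0 * n_d / n_gain),
        }
    return {"n_O": n_o, "n_T": n_t, "n_D": n_d, "n_gain": n_gain, **shares}


def gain_composition(
    es: EventSummary,
    branch: str,
    annotations: Mapping[str, str],
) -> pd.Series:
    """COG-category composition of the families gained on a branch."""
    es.branch(branch)  # raises on unknown branch
    fams = es.gained.get(branch, [])
    return category_composition(fams, annotations)
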