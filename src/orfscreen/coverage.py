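"""Sequencing-based library-representation QC.

After integrating a pooled ORF collection into cells, the library is PCR
amplified and shotgun sequenced; per-base read depth along each ORF tells
which clones made it through cloning, packaging and infection. This module
summarizes per-base depth, applies the presence rule ("at least 95% of the
sequence at a minimum of 10x coverage"), and computes the size-vs-abundance
diagnostic (short clones tend to be over-represented).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ParameterError
from .simulate import AbundanceState

__all__ = [
    "CoverageSummary",
    "DEFAULT_THRESHOLDS",
    "summarize_coverage",
    "call_presence",
    "presence_report",
    "library_presence_rate",
    "size_abundance_trend",
    "read_coverage_tsv",
    "write_coverage_tsv",
    "read_bedgraph",
    "write_bedgraph",
]

#: Depth thresholds bracketing the 10x presence rule.
DEFAULT_THRESHOLDS = (1, 5, 10, 20, 50)


@dataclass(frozen=True)
class CoverageSummary:
    """Mean depth and the fraction of bases at or above each depth threshold."""

    orf_id: str
    length: int
    mean_depth: float
    frac_at_or_above: Mapping[int, float] = field(default_factory=dict)


def summarize_coverage(
    depths: np.ndarray,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    orf_id: str = "",
) -> CoverageSummary:
    """Summarize a per-base depth vector.

    ``frac_at_or_above[c]`` is the fraction of bases with depth >= c; it is
    non-increasing in c by construction.
    """
    depths = np.asarray(depths)
    if depths.size == 0:
        raise ParameterError("empty depth vector")
    if (depths < 0).any():
        raise ParameterError("depths must be non-negative")
    thresholds = tuple(int(t) for t in thresholds)
    if not thresholds or any(t < 1 for t in thresholds):
        raise ParameterError("thresholds must be a non-empty list of positive ints")
    frac = {c: float((depths >= c).mean()) for c in thresholds}
    return CoverageSummary(
        orf_id=orf_id,
        length=int(depths.size),
        mean_depth=float(depths.mean()),
        frac_at_or_above=frac,
    )


def call_presence(
    summary: CoverageSummary,
    min_fraction: float = 0.95,
    min_depth: int = 10,
) -> bool:
    """Apply the presence rule: at least ``min_fraction`` of bases at
    >= ``min_depth`` coverage. The boundary is inclusive ("at least 95%")."""
    if not 0.0 < min_fraction <= 1.0:
        raise ParameterError("min_fraction must lie in (0, 1]")
    if min_depth not in summary.frac_at_or_above:
        raise ParameterError(
            f"min_depth {min_depth} was not among the summarized thresholds "
            f"{sorted(summary.frac_at_or_above)}"
        )
    return summary.frac_at_or_above[min_depth] >= min_fraction


def presence_report(
    summaries: Iterable[CoverageSummary],
    mappable: Mapping[str, bool] | None = None,
    min_fraction: float = 0.95,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Tabulate presence calls over a library.

    ``mappable`` flags come from the annotation (defaulting to True); an
    unmappable ORF is never called present. Columns: ``orf_id, length,
    mean_depth, frac_ge_<min_depth>, mappable, present``.
    """
    rows = []
    for s in summaries:
        is_mappable = True if mappable is None else bool(mappable.get(s.orf_id, True))
        rows.append(
            {
                "orf_id": s.orf_id,
                "length": s.length,
                "mean_depth": s.mean_depth,
                f"frac_ge_{min_depth}": s.frac_at_or_above.get(min_depth, np.nan),
                "mappable": is_mappable,
                "present": is_mappable and call_presence(s, min_fraction, min_depth),
            }
        )
    return pd.DataFrame(rows)


def library_presence_rate(report: pd.DataFrame) -> float:
    """Fraction of mappable ORFs called present."""
    mappable = report["mappable"].to_numpy(dtype=bool)
    if not mappable.any():
        raise ParameterError("no mappable ORFs: presence rate undefined")
    present = report["present"].to_numpy(dtype=bool)
    return float((present & mappable).sum() / mappable.sum())


def size_abundance_trend(
    state: AbundanceState,
    library: pd.DataFrame,
    n_bins: int = 10,
) -> dict:
    """Quantify the size-dependence of library representation.

    Returns the Spearman rank correlation between insert length and count
    (negative = smaller clones over-represented) plus median counts per
    length decile. Raises :class:`DegenerateDataError` when lengths are
    constant (the rank correlation is undefined).
    """
    lengths = library["length_nt"].to_numpy(dtype=float)
    counts = state.counts
    if lengths.size < 10:
        raise ParameterError("need at least 10 ORFs for a trend estimate")
    if np.ptp(lengths) == 0:
        raise DegenerateDataError("all ORF lengths equal: correlation undefined")
    rho, _ = stats.spearmanr(lengths, counts)
    decile = pd.qcut(lengths, q=n_bins, duplicates="drop")
    binned = (
        pd.DataFrame({"length_bin": decile, "count": counts})
        .groupby("length_bin", observed=True)["count"]
        .median()
        .rename("median_count")
        .reset_index()
    )
    return {"spearman_rho": float(rho), "binned_medians": binned}


# ---------------------------------------------------------------------------
# plain-text I/O: per-base TSV and bedGraph (0-based, half-open)

def write_coverage_tsv(profiles: Mapping[str, np.ndarray], path) -> None:
    """Write per-base depth as a 3-column TSV: orf_id, position, depth."""
    frames = [
        pd.DataFrame({"orf_id": orf, "position": np.arange(d.size), "depth": d})
        for orf, d in profiles.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for orf, grp in df.groupby("orf_id", sort=False):
        grp = grp.sort_values("position")
        depth = np.zeros(int(grp["position"].max()) + 1, dtype=np.int64)
        depth[grp["position"].to_numpy()] = grp["depth"].to_numpy()
        out[str(orf)] = depth
    return out


def write_bedgraph(profiles: Mapping[str, np.ndarray], path) -> None:
    """Write run-length-encoded depth: orf_id, start, end, depth (0-based,
    half-open), one run per line, zero runs included so lengths round-trip."""
    with open(path, "w") as fh:
        for orf, depth in profiles.items():
            depth = np.asarray(depth)
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [depth.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{orf}\t{s}\t{e}\t{depth[s]}\n")


def read_bedgraph(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", names=["orf_id", "start", "end", "depth"])
    out = {}
    for orf, grp in df.groupby("orf_id", sort=False):
        depth = np.zeros(int(grp["end"].max()), dtype=np.int64)
        for s, e, d in zip(grp["start"], grp["end"], grp["depth"]):
            depth[int(s): int(e)] = int(d)
        out[str(orf)] = depth
    return out
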