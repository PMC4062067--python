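"""Enrichment-based hit calling for pooled resistance screens.

The screen readout is a paired two-channel intensity per ORF: cells selected
in drug versus cells grown in vehicle (DMSO). Hits are called on the
classic scatter coordinates

    x = log2(I_drug)          (absolute signal under selection)
    y = log2(I_drug / I_DMSO) (enrichment over the unselected pool)

with the dual rule y > 3 and x > 6 (strict, per-replicate), then intersected
across replicates (at least two independent screens), ranked by mean
enrichment, and finally annotated for cross-hybridization: a hit whose probe
is declared similar to a more intense ORF may owe its signal to bleed from
that partner rather than to genuine resistance (the documented false-positive
mode of near-identical paralogs).

No between-array normalization is applied by default; an optional
median-scaling switch exists for real data.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import OrfMismatchError, ParameterError

__all__ = [
    "compute_enrichment",
    "call_hits",
    "consensus_hits",
    "rank_hits",
    "flag_crosshyb",
    "median_scale",
    "call_hits_pipeline",
    "Y_MIN_DEFAULT",
    "X_MIN_DEFAULT",
]

#: Default dual thresholds: log2 ratio > 3 and log2 drug intensity > 6.
Y_MIN_DEFAULT = 3.0
X_MIN_DEFAULT = 6.0


def compute_enrichment(
    drug: pd.Series,
    ctrl: pd.Series,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Compute per-ORF enrichment coordinates for one replicate pair.

    Both channels are floored before taking logs, so x and y are always
    finite. Returns a DataFrame indexed by orf_id with columns ``x`` and
    ``y`` satisfying ``y = x - log2(max(I_dmso, floor))`` exactly.
    """
    if floor <= 0:
        raise ParameterError("floor must be > 0")
    d_idx, c_idx = set(drug.index), set(ctrl.index)
    if d_idx != c_idx:
        diff = sorted(d_idx.symmetric_difference(c_idx))
        raise OrfMismatchError(
            f"drug and control channels index different ORFs; "
            f"symmetric difference: {diff[:20]}"
        )
    ctrl = ctrl.reindex(drug.index)
    x = np.log2(np.maximum(drug.to_numpy(dtype=float), floor))
    y = x - np.log2(np.maximum(ctrl.to_numpy(dtype=float), floor))
    out = pd.DataFrame({"x": x, "y": y}, index=drug.index)
    out.index.name = "orf_id"
    return out


def call_hits(
    table: pd.DataFrame,
    y_min: float = Y_MIN_DEFAULT,
    x_min: float = X_MIN_DEFAULT,
) -> set[str]:
    """Dual-threshold rule: {i : y_i > y_min and x_i > x_min}, strict."""
    if not np.isfinite(table[["x", "y"]].to_numpy()).all():
        raise ParameterError("enrichment table contains non-finite values")
    mask = (table["y"] > y_min) & (table["x"] > x_min)
    return set(table.index[mask])


def consensus_hits(
    per_replicate_hits: Sequence[Iterable[str]],
    min_support: int = 2,
) -> dict[str, int]:
    """ORFs hit in at least ``min_support`` replicates, with support counts.

    Order of the replicate sets does not matter.
    """
    if min_support < 1:
        raise ParameterError("min_support must be >= 1")
    sets = [set(s) for s in per_replicate_hits]
    if len(sets) < min_support:
        raise ParameterError(
            f"{len(sets)} replicate hit sets supplied but min_support={min_support}"
        )
    support: dict[str, int] = {}
    for s in sets:
        for orf in s:
            support[orf] = support.get(orf, 0) + 1
    return {orf: k for orf, k in support.items() if k >= min_support}


def rank_hits(
    consensus: Mapping[str, int],
    tables: Sequence[pd.DataFrame],
) -> pd.DataFrame:
    """Rank consensus hits by mean enrichment across replicates.

    Sort key: mean y descending, ties by mean x descending, residual ties by
    orf_id — fully deterministic. Every consensus ORF must appear in every
    replicate table. Returns columns ``orf_id, mean_x, mean_y, support,
    crosshyb_flag, rank`` plus per-replicate x/y columns.
    """
    if not tables:
        raise ParameterError("at least one enrichment table required")
    orfs = sorted(consensus)
    for k, t in enumerate(tables, start=1):
        missing = [o for o in orfs if o not in t.index]
        if missing:
            raise OrfMismatchError(
                f"replicate table {k} lacks consensus ORFs: {missing[:20]}"
            )
    rows = []
    for orf in orfs:
        row = {"orf_id": orf, "support": consensus[orf], "crosshyb_flag": False}
        xs, ys = [], []
        for k, t in enumerate(tables, start=1):
            row[f"x_rep{k}"] = float(t.at[orf, "x"])
            row[f"y_rep{k}"] = float(t.at[orf, "y"])
            xs.append(row[f"x_rep{k}"])
            ys.append(row[f"y_rep{k}"])
        row["mean_x"] = float(np.mean(xs))
        row["mean_y"] = float(np.mean(ys))
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["orf_id", "mean_x", "mean_y", "support", "crosshyb_flag", "rank"]
        )
    out = out.sort_values(
        ["mean_y", "mean_x", "orf_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def flag_crosshyb(
    hit_table: pd.DataFrame,
    similarity_pairs: Sequence[tuple[str, str, float]],
    flag_threshold: float = 0.2,
    mean_x_lookup: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Annotate hits that may be cross-hybridization artifacts.

    Pairs are directed ``(probe, source, weight)``: the probe receives a
    fraction ``weight`` of the source ORF's signal. A hit on the probe is
    flagged when its declared source has mean drug-channel signal at least
    as high and the weight reaches ``flag_threshold``. Flags annotate, they
    never remove hits. ``mean_x_lookup`` supplies mean x for sources that
    are not themselves hits; a pair naming an ORF unknown to both sources is
    an error.
    """
    out = hit_table.copy()
    if "crosshyb_flag" not in out.columns:
        out["crosshyb_flag"] = False
    known_x: dict[str, float] = dict(zip(out["orf_id"], out["mean_x"]))
    if mean_x_lookup is not None:
        for orf, x in mean_x_lookup.items():
            known_x.setdefault(str(orf), float(x))
    for a, b, w in similarity_pairs:
        if not 0.0 < w <= 1.0:
            raise ParameterError("similarity weights must lie in (0, 1]")
        for orf in (a, b):
            if orf not in known_x:
                raise OrfMismatchError(f"similarity pair references unknown ORF {orf!r}")
        if w < flag_threshold:
            continue
        in_hits = out["orf_id"] == a
        if in_hits.any() and known_x[b] >= known_x[a]:
            out.loc[in_hits, "crosshyb_flag"] = True
    return out


def median_scale(intensities: pd.DataFrame) -> pd.DataFrame:
    """Optional between-array normalization: scale each sample so its median
    intensity equals the across-sample median of medians. Off by default in
    the pipeline."""
    medians = intensities.median(axis=0)
    target = float(medians.median())
    return intensities * (target / medians)


def call_hits_pipeline(
    intensities: pd.DataFrame,
    samples: pd.DataFrame,
    y_min: float = Y_MIN_DEFAULT,
    x_min: float = X_MIN_DEFAULT,
    min_support: int = 2,
    floor: float = 1.0,
    normalize: bool = False,
    similarity_pairs: Sequence[tuple[str, str, float]] | None = None,
    flag_threshold: float = 0.2,
) -> pd.DataFrame:
    """End-to-end hit calling from an intensity matrix and a sample sheet.

    The sample sheet pairs each drug sample with its DMSO control explicitly
    via ``pair_id`` (pairing is never inferred from column order). Hits are
    called per replicate, intersected at ``min_support``, ranked, and
    cross-hybridization flagged.
    """
    required = {"sample_id", "channel", "replicate", "pair_id"}
    if not required.issubset(samples.columns):
        raise ParameterError(f"sample sheet must have columns {sorted(required)}")
    if normalize:
        intensities = median_scale(intensities)
    tables = []
    for pair_id, grp in samples.groupby("pair_id", sort=True):
        chans = grp.set_index("channel")["sample_id"]
        if set(chans.index) != {"drug", "dmso"} or len(grp) != 2:
            raise ParameterError(
                f"pair {pair_id!r} must contain exactly one drug and one dmso sample"
            )
        tables.append(
            compute_enrichment(
                intensities[chans["drug"]], intensities[chans["dmso"]], floor=floor
            )
        )
    per_rep = [call_hits(t, y_min=y_min, x_min=x_min) for t in tables]
    consensus = consensus_hits(per_rep, min_support=min_support)
    ranked = rank_hits(consensus, tables)
    if similarity_pairs:
        lookup = {
            orf: float(np.mean([t.at[orf, "x"] for t in tables]))
            for t in tables for orf in t.index
        }
        ranked = flag_crosshyb(
            ranked, similarity_pairs, flag_threshold=flag_threshold,
            mean_x_lookup=lookup,
        )
    return ranked
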