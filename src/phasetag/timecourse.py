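"""Replicate aggregation, persistence classification, and the expression proxy.

A strain's behavior over a growth experiment is summarized by the fraction of
condensate-containing cells at each timepoint, averaged over biological
replicates (mean and sample SD, ddof=1 -- with the usual n=3 replicates the
n-1 denominator matters).  Persistence is read off the replicate means
against the strain-level cutoff: *persistent* if the final timepoint is at or
above the cutoff, *transient* if some earlier timepoint reached the cutoff
but the final one did not (condensates assembled during growth and
disassembled again), *none* otherwise.

The expression proxy is total fluorescence divided by optical density -- a
stand-in for intracellular protein concentration -- with optional blank
subtraction of both channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .call import DEFAULT_CUTOFF, FractionResult
from .errors import AlignmentError, EmptyInputError, InsufficientDataError

logger = logging.getLogger(__name__)

PersistenceClass = Literal["none", "transient", "persistent"]

FractionLike = Union[FractionResult, float]


@dataclass
class StrainTimecourse:
    """Per-timepoint condensate fractions for one strain across replicates."""

    variant: str
    times: tuple[float, ...]  # hours post-induction, ascending
    fractions: pd.DataFrame  # columns: replicate, time, fraction
    mean: dict[float, float]
    sd: dict[float, float]
    net_charge: Optional[int] = None


def _as_fraction(x: FractionLike) -> float:
    value = x.fraction if isinstance(x, FractionResult) else float(x)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"fraction {value} outside [0, 1]")
    return value


def aggregate(
    per_replicate_fractions: Mapping[str, Mapping[float, FractionLike]],
    variant: str = "",
    net_charge: Optional[int] = None,
) -> StrainTimecourse:
    """Mean and sample SD of condensate fractions across replicates.

    ``per_replicate_fractions`` maps replicate id -> {time_h: fraction}.  All
    replicates must cover the same timepoints; mismatches raise
    :class:`~phasetag.errors.AlignmentError` naming the offenders.  With a
    single replicate the SD is 0 at every timepoint.
    """
    if not per_replicate_fractions:
        raise EmptyInputError("no replicates given")
    reps = {rep: dict(series) for rep, series in per_replicate_fractions.items()}
    for rep, series in reps.items():
        if not series:
            raise EmptyInputError(f"replicate {rep!r} has no timepoints")

    reference = set(next(iter(reps.values())))
    offenders = [
        rep for rep, series in reps.items() if set(series) != reference
    ]
    if offenders:
        raise AlignmentError(
            f"replicates disagree on timepoints: {sorted(offenders)} "
            f"do not match the reference set {sorted(reference)}"
        )

    times = tuple(sorted(reference))
    rows = [
        dict(replicate=rep, time=t, fraction=_as_fraction(series[t]))
        for rep, series in reps.items()
        for t in times
    ]
    df = pd.DataFrame(rows)
    mean = {t: float(df.loc[df.time == t, "fraction"].mean()) for t in times}
    if len(reps) == 1:
        sd = {t: 0.0 for t in times}
    else:
        sd = {t: float(df.loc[df.time == t, "fraction"].std(ddof=1)) for t in times}
    return StrainTimecourse(
        variant=variant, times=times, fractions=df, mean=mean, sd=sd,
        net_charge=net_charge,
    )


def persistence_class(
    tc: StrainTimecourse,
    cutoff: float = DEFAULT_CUTOFF,
) -> PersistenceClass:
    """Classify a strain's condensate behavior over the time course.

    Uses the replicate-mean fraction at each timepoint.  Requires at least two
    timepoints (a final one and something earlier); inserting extra
    sub-cutoff timepoints never changes the class.
    """
    if len(tc.times) < 2:
        raise InsufficientDataError(
            f"need >= 2 timepoints to classify persistence, got {len(tc.times)}"
        )
    final = tc.times[-1]
    if tc.mean[final] >= cutoff:
        return "persistent"
    if any(tc.mean[t] >= cutoff for t in tc.times[:-1]):
        return "transient"
    return "none"


def expression_proxy(
    curve: pd.DataFrame,
    od_blank: float | Sequence[float] = 0.0,
    fluorescence_blank: float | Sequence[float] = 0.0,
) -> pd.DataFrame:
    """Fluorescence/OD ratio over time, a proxy for intracellular concentration.

    ``curve`` must have strictly increasing ``time`` and columns ``od`` and
    ``fluorescence``.  Blanks (scalar or per-timepoint) are subtracted from
    both channels first; points where the blanked OD is not positive are
    masked (NaN proxy) with a warning.
    """
    for col in ("time", "od", "fluorescence"):
        if col not in curve.columns:
            raise ValueError(f"growth table is missing column {col!r}")
    t = curve["time"].to_numpy(dtype=float)
    if len(t) == 0:
        raise EmptyInputError("empty growth table")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    od = curve["od"].to_numpy(dtype=float) - np.asarray(od_blank, dtype=float)
    fluor = curve["fluorescence"].to_numpy(dtype=float) - np.asarray(
        fluorescence_blank, dtype=float
    )
    valid = od > 0
    if not valid.all():
        logger.warning(
            "masking %d of %d proxy points with non-positive blanked OD",
            (~valid).sum(), len(valid),
        )
    proxy = np.full_like(od, np.nan)
    proxy[valid] = fluor[valid] / od[valid]
    out = curve.copy()
    out["proxy"] = proxy
    return out
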