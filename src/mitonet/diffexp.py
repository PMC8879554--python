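"""Reference-spot normalization, median logFC and bootstrap effect sizes.

The analysis model: each 2D gel carries an unknown multiplicative loading/
staining factor shared by every spot on the gel.  Dividing every spot
intensity by the same gel's reference (albumin) spot intensity cancels that
factor exactly.  Group differences are then summarized as the log ratio of
group *medians* of normalized intensities, and uncertainty is quantified by
resampling gels (the independent biological replicates) with replacement
within each group before recomputing the logFC.  A protein is called
differential when the absolute bootstrap effect size exceeds a strict
threshold (default 0.5 on the log2 scale).
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SpotIntensityTable, ValidationError

__all__ = [
    "NormalizedTable",
    "DifferentialResult",
    "normalize",
    "logfc",
    "bootstrap_effect",
    "bootstrap_table",
    "call_differential",
]

DEFAULT_THRESHOLD = 0.5  # strict: |effect| must exceed, not reach, this value


@dataclass(frozen=True)
class NormalizedTable:
    """Spot intensities divided by the gel's reference-spot intensity.

    Dimensionless; the reference row is exactly 1.0 in every gel, and the
    table is invariant under any per-gel rescaling of the raw intensities.
    """

    values: pd.DataFrame
    gel_to_group: Mapping[str, str]
    reference_spot_id: str

    @property
    def spot_ids(self) -> list:
        return list(self.values.index)

    @property
    def gel_ids(self) -> list:
        return list(self.values.columns)

    def gels_in_group(self, group: str) -> list:
        return [g for g in self.gel_ids if self.gel_to_group[g] == group]

    def group_values(self, spot, group: str) -> np.ndarray:
        gels = self.gels_in_group(group)
        if not gels:
            raise ValidationError(f"group {group!r} has no gels")
        return self.values.loc[spot, gels].to_numpy(dtype=float)


@dataclass(frozen=True)
class DifferentialResult:
    """Bootstrap summary of one spot under one contrast.

    ``contrast`` is the ordered ``(numerator, denominator)`` group pair;
    ``logfc_point`` is the plug-in log ratio of group medians;
    ``effect_size`` is the median of the bootstrap logFC distribution with
    ``(ci_low, ci_high)`` its percentile interval.  ``n_boot_used`` counts
    replicates that survived (a replicate fails when a resampled group
    median is zero).
    """

    spot_id: str
    contrast: tuple[str, str]
    logfc_point: float
    effect_size: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_boot_used: int
    is_differential: bool
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        if not (self.ci_low <= self.effect_size <= self.ci_high):
            raise ValidationError(
                f"effect size {self.effect_size} outside its interval "
                f"[{self.ci_low}, {self.ci_high}]"
            )


def normalize(table) -> NormalizedTable:
    """Divide every spot's intensity by the same gel's reference intensity.

    Accepts a raw :class:`SpotIntensityTable` or an already-normalized
    table (on which it is the identity, since the reference row is 1).
    """
    if isinstance(table, NormalizedTable):
        df = table.values
    elif isinstance(table, SpotIntensityTable):
        df = table.intensities
    else:
        raise TypeError(f"cannot normalize {type(table).__name__}")
    ref = df.loc[table.reference_spot_id]
    bad = [g for g in df.columns if not ref[g] > 0]
    if bad:
        raise ValidationError(
            f"reference spot {table.reference_spot_id!r} is zero or missing "
            f"in gels: {bad}"
        )
    return NormalizedTable(df.div(ref, axis=1), dict(table.gel_to_group), table.reference_spot_id)


def _log_ratio(a: float, b: float, log_base: float) -> float:
    # computed as log(a) - log(b) so that logfc(a,b) == -logfc(b,a) exactly
    return (math.log(a) - math.log(b)) / math.log(log_base)


def logfc(
    norm: NormalizedTable,
    spot,
    group_a: str,
    group_b: str,
    log_base: float = 2.0,
) -> float:
    """log of (median of group_a / median of group_b), base 2 by default.

    Raises if either group median is zero — no pseudocount is applied.
    """
    med_a = float(np.median(norm.group_values(spot, group_a)))
    med_b = float(np.median(norm.group_values(spot, group_b)))
    if med_a <= 0 or med_b <= 0:
        raise ValidationError(
            f"zero group median for spot {spot!r} "
            f"({group_a}={med_a}, {group_b}={med_b}); cannot take log"
        )
    return _log_ratio(med_a, med_b, log_base)


def bootstrap_effect(
    norm: NormalizedTable,
    spot,
    group_a: str,
    group_b: str,
    n_boot: int = 1000,
    seed=0,
    threshold: float = DEFAULT_THRESHOLD,
    ci: tuple[float, float] = (2.5, 97.5),
    log_base: float = 2.0,
) -> DifferentialResult:
    """Bootstrap the logFC by resampling gels with replacement per group.

    For each replicate the gels of each group are independently resampled
    with replacement (resample size = group size) and the median-based
    logFC recomputed.  The effect size is the median of the replicate
    distribution; the interval is the (2.5, 97.5) percentile interval by
    default.  Replicates with a zero resampled median are excluded and
    counted in ``n_boot - n_boot_used``.
    """
    if n_boot < 1:
        raise ValidationError(f"n_boot must be >= 1, got {n_boot}")
    va = norm.group_values(spot, group_a)
    vb = norm.group_values(spot, group_b)
    if len(va) < 2 or len(vb) < 2:
        raise ValidationError(
            f"bootstrap needs >= 2 gels per group "
            f"({group_a}: {len(va)}, {group_b}: {len(vb)})"
        )
    point = logfc(norm, spot, group_a, group_b, log_base=log_base)

    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, len(va), size=(n_boot, len(va)))
    idx_b = rng.integers(0, len(vb), size=(n_boot, len(vb)))
    med_a = np.median(va[idx_a], axis=1)
    med_b = np.median(vb[idx_b], axis=1)
    ok = (med_a > 0) & (med_b > 0)
    if not ok.any():
        raise ValidationError(
            f"all {n_boot} bootstrap replicates failed for spot {spot!r} "
            f"(zero resampled medians)"
        )
    reps = (np.log(med_a[ok]) - np.log(med_b[ok])) / np.log(log_base)
    effect = float(np.median(reps))
    lo, hi = (float(x) for x in np.percentile(reps, ci))
    return DifferentialResult(
        spot_id=spot,
        contrast=(group_a, group_b),
        logfc_point=point,
        effect_size=effect,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        n_boot_used=int(ok.sum()),
        is_differential=abs(effect) > threshold,
        threshold=threshold,
    )


def bootstrap_table(
    norm: NormalizedTable,
    contrasts: Sequence[tuple[str, str]],
    n_boot: int = 1000,
    seed=0,
    threshold: float = DEFAULT_THRESHOLD,
    log_base: float = 2.0,
) -> list[DifferentialResult]:
    """Bootstrap every spot under every contrast with per-task child seeds.

    Child seeds are spawned deterministically (spot-major order) from the
    master seed, so a single spot recomputed in isolation with its child
    seed reproduces the table-wide result.
    """
    spots = norm.spot_ids
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(spots) * len(contrasts))
    results = []
    k = 0
    for spot in spots:
        for (a, b) in contrasts:
            results.append(
                bootstrap_effect(
                    norm,
                    spot,
                    a,
                    b,
                    n_boot=n_boot,
                    seed=children[k],
                    threshold=threshold,
                    log_base=log_base,
                )
            )
            k += 1
    return results


def call_differential(
    results: Iterable[DifferentialResult],
    threshold: float | None = None,
    reference_spot_id=None,
) -> dict[tuple[str, str], frozenset]:
    """Differential spot set per contrast: ``|effect_size| > threshold``.

    The comparison is strict, so an effect of exactly the threshold is not
    called.  The reference spot is always excluded.
    """
    if threshold is not None and not threshold > 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    out: dict[tuple[str, str], set] = {}
    for res in results:
        out.setdefault(res.contrast, set())
        if res.spot_id == reference_spot_id:
            continue
        hit = (
            res.is_differential
            if threshold is None
            else abs(res.effect_size) > threshold
        )
        if hit:
            out[res.contrast].add(res.spot_id)
    return {c: frozenset(s) for c, s in out.items()}
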