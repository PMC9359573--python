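"""ΔCT-based kdr genotype calling for the dual-probe RTkdr assay.

One specimen yields two cycle-threshold values: CT of the FAM-labelled
wild-type (TTA) probe and CT of the HEX-labelled mutant (TTT) probe.
The genotyping statistic is

    ΔCT = CT_TTT - CT_TTA

with an absent CT replaced by 40 (the final cycle). Early TTA relative to TTT
(large positive ΔCT) means only the wild-type allele is present (LL); the
mirror case is FF; both probes amplifying together (ΔCT near 0) is the LF
heterozygote. Calls are made either by 1-D k-means with k=3 (cluster order
maps FF < LF < LL) or by fixed per-species ΔCT decision bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import tables

CT_MAX = 40.0

GENOTYPES = ("FF", "LF", "LL")

FLAG_TTA_SUB = "tta_substituted_40"
FLAG_TTT_SUB = "ttt_substituted_40"
FLAG_NO_AMP = "no_amplification"
FLAG_GAP = "in_band_gap"
FLAG_TIE = "cluster_tie"


@dataclass
class WellReading:
    """One specimen's dual-probe record. ``ct_tta``/``ct_ttt`` are cycle
    thresholds in (0, 40], or None if the probe never crossed threshold.
    ``curve_tta``/``curve_ttt`` optionally hold per-cycle ΔRn series."""

    specimen_id: str
    species: str = ""
    ct_tta: float | None = None
    ct_ttt: float | None = None
    curve_tta: list[float] | None = None
    curve_ttt: list[float] | None = None

    def __post_init__(self):
        for name in ("ct_tta", "ct_ttt"):
            ct = getattr(self, name)
            if ct is not None and not (0 < ct <= CT_MAX):
                raise ValueError(
                    f"specimen {self.specimen_id!r}: {name}={ct} outside (0, {CT_MAX}]"
                )


@dataclass
class GenotypeCall:
    specimen_id: str
    delta_ct: float
    genotype: str  # LL | LF | FF | UNDETERMINED | EXCLUDED
    method: str    # cluster | threshold
    cluster_index: int | None = None
    flags: frozenset[str] = field(default_factory=frozenset)


def ct_from_curve(curve, threshold_frac: float = 0.1) -> float | None:
    """Threshold-crossing CT from a per-cycle ΔRn series: the (interpolated)
    first cycle at which the baseline-subtracted signal exceeds
    ``threshold_frac`` of the plateau; None if it never does or the curve is
    flat. A documented stand-in for instrument-reported CTs."""
    y = np.asarray(curve, dtype=float)
    if y.size == 0:
        return None
    plateau = float(np.nanmax(y))
    if plateau <= 0:
        return None
    thr = threshold_frac * plateau
    above = np.nonzero(y >= thr)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return 1.0
    # cycles are 1-based; interpolate between cycle i and i+1
    frac = (thr - y[i - 1]) / (y[i] - y[i - 1])
    return float(i + frac)


def compute_delta_ct(
    reading: WellReading, ct_max: float = CT_MAX
) -> tuple[float, frozenset[str]]:
    """ΔCT = CT_TTT - CT_TTA, substituting ``ct_max`` for an absent probe.

    Returns (nan, {no_amplification}) when both probes failed.
    """
    tta, ttt = reading.ct_tta, reading.ct_ttt
    if tta is None and ttt is None and reading.curve_tta is not None:
        tta = ct_from_curve(reading.curve_tta)
        ttt = ct_from_curve(reading.curve_ttt) if reading.curve_ttt is not None else None
    flags = set()
    if tta is None and ttt is None:
        return float("nan"), frozenset([FLAG_NO_AMP])
    if tta is None:
        tta = ct_max
        flags.add(FLAG_TTA_SUB)
    if ttt is None:
        ttt = ct_max
        flags.add(FLAG_TTT_SUB)
    return float(ttt - tta), frozenset(flags)


def qc_filter(
    readings: list[WellReading], cutoff_cycle: float = 30.0
) -> tuple[list[WellReading], list[WellReading]]:
    """Exclude specimens that failed to amplify a product by ``cutoff_cycle``:
    every present CT exceeds the cutoff, or no probe amplified at all."""
    kept, excluded = [], []
    for r in readings:
        cts = [c for c in (r.ct_tta, r.ct_ttt) if c is not None]
        if not cts or all(c > cutoff_cycle for c in cts):
            excluded.append(r)
        else:
            kept.append(r)
    return kept, excluded


# --- 1-D k-means -------------------------------------------------------------

@dataclass
class ClusterModel:
    centers: np.ndarray            # sorted ascending
    assignments: np.ndarray        # index into centers, per input value
    iterations: int
    converged: bool
    inertia: float


def _lloyd(values: np.ndarray, centers: np.ndarray, max_iter: int):
    assign = np.full(values.size, -1, dtype=int)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # nearest center; exact ties go to the lower index (argmin behaviour)
        d = np.abs(values[:, None] - centers[None, :])
        new_assign = np.argmin(d, axis=1)
        if np.array_equal(new_assign, assign):
            converged = True
            break
        assign = new_assign
        for k in range(centers.size):
            members = values[assign == k]
            if members.size:
                centers[k] = members.mean()
            else:  # re-seed an empty cluster at the worst-fit point
                far = np.argmax(np.abs(values - centers[assign]))
                centers[k] = values[far]
    inertia = float(np.sum((values - centers[assign]) ** 2))
    return centers, assign, it, converged, inertia


def kmeans_1d(
    values,
    k: int = 3,
    max_iter: int = 10,
    restarts: int = 8,
    seed: int | None = None,
) -> ClusterModel:
    """Lloyd's algorithm on 1-D data: deterministic quantile initialisation at
    the (2i+1)/2k quantiles, plus ``restarts`` seeded random restarts; the
    solution with the smallest within-cluster sum of squares is kept. Centers
    are returned ascending with assignments relabelled to match."""
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < k:
        raise ValueError(f"need at least {k} distinct values")
    rng = np.random.default_rng(seed)

    inits = [np.quantile(values, [(2 * i + 1) / (2 * k) for i in range(k)])]
    uniq = np.unique(values)
    for _ in range(restarts):
        inits.append(np.sort(rng.choice(uniq, size=k, replace=False)))

    best = None
    for init in inits:
        result = _lloyd(values.copy(), np.asarray(init, dtype=float).copy(), max_iter)
        if best is None or result[4] < best[4]:
            best = result
    centers, assign, it, converged, inertia = best
    if not converged:
        warnings.warn(f"k-means hit the {max_iter}-iteration cap without converging")

    order = np.argsort(centers)
    relabel = np.empty_like(order)
    relabel[order] = np.arange(k)
    return ClusterModel(
        centers=centers[order],
        assignments=relabel[assign],
        iterations=it,
        converged=converged,
        inertia=inertia,
    )


def calls_from_clusters(
    model: ClusterModel,
    delta_cts,
    specimen_ids=None,
) -> list[GenotypeCall]:
    """Map the three ΔCT clusters to genotypes by center order:
    lowest -> FF, middle -> LF, highest -> LL. A ΔCT exactly midway between
    two centers is assigned to the lower-index cluster and flagged."""
    centers = np.asarray(model.centers, dtype=float)
    if centers.size != 3:
        raise ValueError("cluster calling requires exactly 3 centers")
    if not np.all(np.isfinite(centers)):
        raise ValueError("non-finite cluster center")
    delta_cts = np.asarray(delta_cts, dtype=float)
    if specimen_ids is None:
        specimen_ids = [str(i) for i in range(delta_cts.size)]

    calls = []
    for sid, d in zip(specimen_ids, delta_cts):
        dist = np.abs(d - centers)
        idx = int(np.argmin(dist))
        tie = np.sum(dist == dist[idx]) > 1
        calls.append(
            GenotypeCall(
                specimen_id=sid,
                delta_ct=float(d),
                genotype=GENOTYPES[idx],
                method="cluster",
                cluster_index=idx,
                flags=frozenset([FLAG_TIE]) if tie else frozenset(),
            )
        )
    return calls


# --- Threshold bands ---------------------------------------------------------

@dataclass(frozen=True)
class ThresholdBands:
    """Per-species ΔCT decision bands: ΔCT > ll_min -> LL, ΔCT < ff_max -> FF,
    lf_low <= ΔCT <= lf_high -> LF; ΔCT in the gaps the printed bands leave is
    UNDETERMINED (the study reviewed such amplification curves manually)."""

    species: str
    ff_max: float
    lf_low: float
    lf_high: float
    ll_min: float

    def __post_init__(self):
        if not (self.ff_max <= self.lf_low <= self.lf_high <= self.ll_min):
            raise ValueError(f"inverted bands for {self.species!r}")


def species_bands(species: str) -> ThresholdBands | None:
    """Published bands for the validated species; None for others (which are
    called by clustering only)."""
    b = tables.THRESHOLD_BANDS.get(species)
    return ThresholdBands(species=species, **b) if b else None


def calls_from_thresholds(
    delta_cts, bands: ThresholdBands, specimen_ids=None
) -> list[GenotypeCall]:
    delta_cts = np.asarray(delta_cts, dtype=float)
    if specimen_ids is None:
        specimen_ids = [str(i) for i in range(delta_cts.size)]
    calls = []
    for sid, d in zip(specimen_ids, delta_cts):
        if d > bands.ll_min:
            geno, flags = "LL", frozenset()
        elif d < bands.ff_max:
            geno, flags = "FF", frozenset()
        elif bands.lf_low <= d <= bands.lf_high:
            geno, flags = "LF", frozenset()
        else:
            geno, flags = "UNDETERMINED", frozenset([FLAG_GAP])
        calls.append(
            GenotypeCall(
                specimen_id=sid, delta_ct=float(d), genotype=geno,
                method="threshold", flags=flags,
            )
        )
    return calls


def anova_delta_by_genotype(delta_cts, genotypes) -> tuple[float, int, int, float]:
    """One-way ANOVA of ΔCT across assigned genotype groups:
    (F, df_between, df_within, p)."""
    delta_cts = np.asarray(delta_cts, dtype=float)
    genotypes = np.asarray(genotypes)
    groups = [delta_cts[genotypes == g] for g in np.unique(genotypes)]
    groups = [g for g in groups if g.size]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two genotype groups")
    f, p = sps.f_oneway(*groups)
    df_between = len(groups) - 1
    df_within = sum(g.size for g in groups) - len(groups)
    return float(f), df_between, df_within, float(p)
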