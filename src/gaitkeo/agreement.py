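"""Agreement statistics between the accelerometer and mocap arms.

Stride-level stance durations from the two systems are paired by nearest
initial-contact time, then compared with the classic method-comparison
toolkit: Kolmogorov-Smirnov normality check of the differences, a
two-sample t test of the stance distributions, Bland-Altman bias and 95 %
limits of agreement (LOA) with a confidence interval on the bias, and a
two-way absolute-agreement single-measures intraclass correlation
(McGraw & Wong ICC(A,1); often reported in the literature under the
Shrout-Fleiss label ICC(2,1) or, loosely, "ICC(3,1)" — absolute agreement
is what distinguishes it: a constant offset between the systems lowers it,
which a consistency ICC would ignore).

Statistics are computed over pooled stride-level pairs by default; a
per-participant-mean mode collapses each participant to one pair first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sst
from statsmodels.stats.diagnostic import lilliefors

from .signal_io import DataError, EventSeries, PairingError

DEFAULT_MATCH_TOLERANCE_S = 0.25


@dataclass(frozen=True)
class StancePair:
    """One stride measured by both systems."""

    stance_accel_s: float
    stance_mocap_s: float
    participant_id: str = "p0"
    side: str = "unknown"
    ic_delta_s: float = 0.0

    @property
    def difference_s(self) -> float:
        return self.stance_accel_s - self.stance_mocap_s

    @property
    def mean_s(self) -> float:
        return 0.5 * (self.stance_accel_s + self.stance_mocap_s)


@dataclass
class PairedStances:
    """One-to-one matched stride pairs across the two systems."""

    pairs: list[StancePair] = field(default_factory=list)
    matching_tolerance_s: float = DEFAULT_MATCH_TOLERANCE_S

    def __post_init__(self) -> None:
        for p in self.pairs:
            if abs(p.ic_delta_s) > self.matching_tolerance_s + 1e-12:
                raise DataError(
                    f"pair with IC time difference {p.ic_delta_s:.3f} s exceeds "
                    f"the matching tolerance {self.matching_tolerance_s:.3f} s"
                )

    @property
    def n(self) -> int:
        return len(self.pairs)

    def accel(self) -> np.ndarray:
        return np.array([p.stance_accel_s for p in self.pairs], dtype=float)

    def mocap(self) -> np.ndarray:
        return np.array([p.stance_mocap_s for p in self.pairs], dtype=float)

    def differences(self) -> np.ndarray:
        return self.accel() - self.mocap()

    def per_participant_means(self) -> "PairedStances":
        """Collapse to one (mean accel, mean mocap) pair per participant."""
        groups: dict[str, list[StancePair]] = {}
        for p in self.pairs:
            groups.setdefault(p.participant_id, []).append(p)
        collapsed = [
            StancePair(
                stance_accel_s=float(np.mean([q.stance_accel_s for q in ps])),
                stance_mocap_s=float(np.mean([q.stance_mocap_s for q in ps])),
                participant_id=pid,
                side="pooled",
            )
            for pid, ps in sorted(groups.items())
        ]
        return PairedStances(pairs=collapsed, matching_tolerance_s=self.matching_tolerance_s)

    def extend(self, other: "PairedStances") -> None:
        self.pairs.extend(other.pairs)


def match_strides(
    accel: EventSeries,
    mocap: EventSeries,
    tolerance_s: float = DEFAULT_MATCH_TOLERANCE_S,
    participant_id: str = "p0",
) -> PairedStances:
    """Greedy one-to-one nearest-neighbour stride matching on IC times.

    Strides are matched within each side separately (sides present in only
    one series are matched against the pool of the other).  Candidate pairs
    are taken in order of increasing |ΔIC|; pairs beyond ``tolerance_s`` and
    strides left unmatched are dropped.  Raises :class:`PairingError` when
    nothing matches.
    """
    sides_a, sides_b = set(accel.sides), set(mocap.sides)
    shared = sides_a & sides_b
    groups = [(s, s) for s in sorted(shared)]
    if not groups:  # fall back to cross-side pooling when labels disagree
        groups = [(None, None)]

    pairs: list[StancePair] = []
    for side_a, side_b in groups:
        sa = [s for s in accel.strides if side_a is None or s.side == side_a]
        sb = [s for s in mocap.strides if side_b is None or s.side == side_b]
        if not sa or not sb:
            continue
        cand = sorted(
            ((abs(x.ic_time - y.ic_time), i, j) for i, x in enumerate(sa) for j, y in enumerate(sb)),
            key=lambda t: t[0],
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        for delta, i, j in cand:
            if delta > tolerance_s:
                break
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            pairs.append(
                StancePair(
                    stance_accel_s=sa[i].stance_s,
                    stance_mocap_s=sb[j].stance_s,
                    participant_id=participant_id,
                    side=sa[i].side,
                    ic_delta_s=sa[i].ic_time - sb[j].ic_time,
                )
            )
    if not pairs:
        raise PairingError(
            f"no stride pairs matched within {tolerance_s:.3f} s of IC time"
        )
    pairs.sort(key=lambda p: (p.participant_id, p.side, p.stance_mocap_s))
    return PairedStances(pairs=pairs, matching_tolerance_s=tolerance_s)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltman:
    n: int
    bias_s: float
    sd_diff_s: float
    loa_low_s: float
    loa_high_s: float
    bias_ci95: tuple[float, float]
    plot_means: np.ndarray
    plot_differences: np.ndarray


def bland_altman(pairs: PairedStances) -> BlandAltman:
    """Bias, SD of differences, 95 % limits of agreement and bias CI.

    d_i = accel − mocap; bias = mean(d); LOA = bias ± 1.96·SD(d);
    95 % CI of the bias uses the t distribution with n−1 df.  Also returns
    the per-pair (mean, difference) coordinates for the agreement plot.
    """
    if pairs.n < 3:
        raise DataError(f"Bland-Altman needs at least 3 pairs, got {pairs.n}")
    d = pairs.differences()
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half = float(sst.t.ppf(0.975, pairs.n - 1)) * sd / np.sqrt(pairs.n)
    return BlandAltman(
        n=pairs.n,
        bias_s=bias,
        sd_diff_s=sd,
        loa_low_s=bias - 1.96 * sd,
        loa_high_s=bias + 1.96 * sd,
        bias_ci95=(bias - half, bias + half),
        plot_means=0.5 * (pairs.accel() + pairs.mocap()),
        plot_differences=d,
    )


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci95: tuple[float, float]
    msr: float
    msc: float
    mse: float
    n: int
    k: int = 2
    defined: bool = True


def icc_single_measures(pairs: PairedStances, alpha: float = 0.05) -> IccResult:
    """Two-way absolute-agreement single-measures ICC from ANOVA mean squares.

    With n subjects (stride pairs) and k=2 raters (measurement systems):

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    where MSR, MSC, MSE are the rows (subjects), columns (systems) and
    residual mean squares of the two-way layout.  The 95 % CI follows the
    McGraw & Wong F-based construction with Satterthwaite df.  When there
    is no between-subject variance the ICC is undefined and flagged.
    """
    if pairs.n < 3:
        raise DataError(f"ICC needs at least 3 pairs, got {pairs.n}")
    table = np.column_stack([pairs.accel(), pairs.mocap()])
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = table - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or np.isclose(msr, 0.0) and np.isclose(mse, 0.0) and np.isclose(msc, 0.0):
        return IccResult(
            icc=float("nan"), ci95=(float("nan"), float("nan")),
            msr=msr, msc=msc, mse=mse, n=n, defined=False,
        )
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) CI for ICC(A,1)
    if mse <= 0:
        ci = (icc, icc)
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
        if np.isfinite(a) and np.isfinite(b):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_l = sst.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = sst.f.ppf(1 - alpha / 2, v, n - 1)
            lower = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            upper = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
            ci = (float(lower), float(upper))
        else:
            ci = (icc, icc)
    return IccResult(icc=float(icc), ci95=ci, msr=float(msr), msc=float(msc),
                     mse=float(mse), n=n)


def icc_consistency(pairs: PairedStances) -> float:
    """Two-way consistency single-measures ICC (offset-blind companion).

    Provided for contrast with the absolute-agreement form: with any
    systematic offset between the systems this is strictly larger.
    """
    table = np.column_stack([pairs.accel(), pairs.mocap()])
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    resid = table - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    return float((msr - mse) / denom) if denom > 0 else float("nan")


# ---------------------------------------------------------------------------
# Normality and location tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KsResult:
    statistic: float
    p_fixed: float
    p_lilliefors: float
    degenerate: bool = False


def ks_normality(
    differences: np.ndarray,
    mean: float | None = None,
    sd: float | None = None,
) -> KsResult:
    """One-sample KS statistic of the differences against a normal law.

    The statistic D = sup|ECDF − Φ| is computed against N(mean, sd²); when
    the parameters are not supplied they are estimated from the data, and in
    that case the fixed-parameter p-value is optimistic, so the
    Lilliefors-corrected p-value is reported alongside it.  Constant input
    is degenerate and flagged rather than tested.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 5:
        raise DataError(f"normality check needs at least 5 values, got {d.size}")
    if np.ptp(d) == 0:  # constant input: no distribution to test
        return KsResult(float("nan"), float("nan"), float("nan"), degenerate=True)
    est_sd = float(np.std(d, ddof=1))
    mu = float(np.mean(d)) if mean is None else float(mean)
    sigma = est_sd if sd is None else float(sd)
    stat, p_fixed = sst.kstest(d, "norm", args=(mu, sigma))
    _, p_lf = lilliefors(d, dist="norm", pvalmethod="table")
    return KsResult(float(stat), float(p_fixed), float(p_lf))


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    welch: bool = False
    degenerate: bool = False


def ttest_two_sample(a: np.ndarray, b: np.ndarray, welch: bool = False) -> TTestResult:
    """Two-sample t test of the stance-duration distributions.

    Pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption.  Zero combined variance is degenerate and
    flagged (T=0, p=1 when the means also coincide).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("t test needs at least 2 values per sample")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        same = np.mean(a) == np.mean(b)
        return TTestResult(
            statistic=0.0 if same else float("inf"),
            p_value=1.0 if same else 0.0,
            welch=welch,
            degenerate=True,
        )
    t, p = sst.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(t), float(p), welch=welch)


# ---------------------------------------------------------------------------
# Assembled report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementReport:
    """All validation statistics for one accelerometer-vs-mocap comparison."""

    n_pairs: int
    mean_accel_s: float
    mean_mocap_s: float
    bias_s: float
    sd_diff_s: float
    loa_low_s: float
    loa_high_s: float
    bias_ci95: tuple[float, float]
    icc_a1: float
    icc_ci95: tuple[float, float]
    icc_defined: bool
    ks_stat: float
    ks_p: float
    ks_p_lilliefors: float
    t_stat: float
    t_p: float
    per_side: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sd_diff_s > 0 and not (self.loa_low_s < self.bias_s < self.loa_high_s):
            raise DataError("limits of agreement must bracket the bias")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bias_ci95"] = list(self.bias_ci95)
        d["icc_ci95"] = list(self.icc_ci95)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementReport":
        d = dict(d)
        d["bias_ci95"] = tuple(d["bias_ci95"])
        d["icc_ci95"] = tuple(d["icc_ci95"])
        return cls(**d)


def pair_walks(
    walks,
    params=None,
    tolerance_s: float = DEFAULT_MATCH_TOLERANCE_S,
    on_error: str = "raise",
) -> PairedStances:
    """Run both detection arms on simulated walks and pool matched strides.

    For every walk and side, detects events from the acceleration trace,
    extracts coordinate-based events from the markers, and matches strides.
    ``on_error="skip"`` drops walk/sides where either arm fails (logged)
    instead of raising.
    """
    from .mocap import zeni_events
    from .simulate import SIDES
    from .tkeo import detect_gait_events
    import logging

    log = logging.getLogger("gaitkeo")
    pooled = PairedStances(matching_tolerance_s=tolerance_s)
    for walk in walks:
        for side in SIDES:
            try:
                accel_events = detect_gait_events(walk.accel[side], params)
                mocap_events = zeni_events(walk.markers, side)
                pooled.extend(
                    match_strides(
                        accel_events,
                        mocap_events,
                        tolerance_s=tolerance_s,
                        participant_id=walk.participant_id,
                    )
                )
            except Exception:
                if on_error != "skip":
                    raise
                log.warning(
                    "skipping %s walk %d side %s after a detection failure",
                    walk.participant_id, walk.walk_index, side, exc_info=True,
                )
    return pooled


def agreement_report(pairs: PairedStances) -> AgreementReport:
    """Run the full statistics battery on matched stride pairs."""
    ba = bland_altman(pairs)
    icc = icc_single_measures(pairs)
    ks = ks_normality(pairs.differences()) if pairs.n >= 5 else KsResult(
        float("nan"), float("nan"), float("nan"), degenerate=True
    )
    tt = ttest_two_sample(pairs.accel(), pairs.mocap())
    per_side: dict[str, dict[str, float]] = {}
    for side in sorted({p.side for p in pairs.pairs}):
        sel = [p for p in pairs.pairs if p.side == side]
        dd = np.array([p.difference_s for p in sel])
        per_side[side] = {
            "n": len(sel),
            "bias_s": float(np.mean(dd)),
            "mean_accel_s": float(np.mean([p.stance_accel_s for p in sel])),
            "mean_mocap_s": float(np.mean([p.stance_mocap_s for p in sel])),
        }
    return AgreementReport(
        n_pairs=pairs.n,
        mean_accel_s=float(np.mean(pairs.accel())),
        mean_mocap_s=float(np.mean(pairs.mocap())),
        bias_s=ba.bias_s,
        sd_diff_s=ba.sd_diff_s,
        loa_low_s=ba.loa_low_s,
        loa_high_s=ba.loa_high_s,
        bias_ci95=ba.bias_ci95,
        icc_a1=icc.icc,
        icc_ci95=icc.ci95,
        icc_defined=icc.defined,
        ks_stat=ks.statistic,
        ks_p=ks.p_fixed,
        ks_p_lilliefors=ks.p_lilliefors,
        t_stat=tt.statistic,
        t_p=tt.p_value,
        per_side=per_side,
    )
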