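"""LA-MC-ICP-MS strontium isotope data reduction and group statistics.

Reduces raw beam-cycle intensities (masses 82–88, volts) to corrected
87Sr/86Sr per laser spot through the standard chain:

1. baseline subtraction (per-spot baseline window mean),
2. Kr isobaric-interference stripping at masses 84 and 86 from the 82Kr
   monitor beam using natural Kr abundances,
3. exponential-law mass bias from the Kr-corrected 88Sr/86Sr against the
   canonical ratio (8.375209),
4. Rb isobaric correction at mass 87 from the 85Rb monitor, with the Rb
   ratio itself mass-bias corrected,
5. internal exponential-law normalisation of 87Sr/86Sr, then
   standard-sample-standard bracketing against a carbonate standard pinned
   to modern seawater (0.709182).

Also provides the per-transect summaries and the group comparisons used
downstream (Welch's t-test, Kruskal–Wallis with Dunn's post-hoc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .constants import SR_CONSTANTS, IsotopeConstants

__all__ = [
    "BeamCycles",
    "SpotAnalysis",
    "ReducedSpot",
    "TransectSummary",
    "baseline_subtract",
    "kr_correct",
    "mass_bias",
    "rb_correct",
    "reduce_spot",
    "normalize_and_bracket",
    "reduce_session",
    "transect_summary",
    "welch_t",
    "kruskal_dunn",
]

MASSES = ("m82", "m83", "m84", "m85", "m86", "m87", "m88")


@dataclass
class BeamCycles:
    """Beam intensities (volts) per cycle for one spot, columns m82..m88."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [m for m in MASSES if m not in self.data.columns]
        if missing:
            raise ValueError(f"missing mass columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class SpotAnalysis:
    """One laser spot: which cycles are baseline vs ablation, and its role."""

    spot_id: str
    baseline: BeamCycles
    ablation: BeamCycles
    role: Literal["sample", "bracketing_standard", "accuracy_standard"] = "sample"
    tooth: str | None = None
    transect: str | None = None
    order: int = 0  # acquisition order within the session


@dataclass
class ReducedSpot:
    spot_id: str
    r87_86: float
    r87_86_2se: float
    r84_86: float
    r87rb_86: float
    beta: float
    role: str = "sample"
    tooth: str | None = None
    transect: str | None = None
    order: int = 0
    flags: list[str] = field(default_factory=list)


@dataclass
class TransectSummary:
    tooth: str
    transect: str
    mean: float
    two_se: float
    n_spots: int


def baseline_subtract(spot: SpotAnalysis) -> BeamCycles:
    """Subtract the per-mass mean of the baseline window from each ablation
    cycle."""
    if len(spot.baseline) < 3:
        raise ValueError("baseline window must contain at least 3 cycles")
    base = spot.baseline.data[list(MASSES)].mean(axis=0)
    net = spot.ablation.data.copy()
    net[list(MASSES)] = net[list(MASSES)] - base
    return BeamCycles(net)


def kr_correct(net: BeamCycles, c: IsotopeConstants = SR_CONSTANTS,
               use_kr83: bool = False) -> BeamCycles:
    """Remove Kr isobaric interference from masses 84 and 86.

    The Kr contribution is predicted from the interference-free 82Kr beam
    via natural abundances; with ``use_kr83`` the predictions from 82Kr and
    83Kr are averaged.
    """
    out = net.data.copy()
    kr84 = out["m82"] * c.kr84_82
    kr86 = out["m82"] * c.kr86_82
    if use_kr83:
        kr84 = 0.5 * (kr84 + out["m83"] * c.kr84_83)
        kr86 = 0.5 * (kr86 + out["m83"] * c.kr86_83)
    out["m84"] = out["m84"] - kr84
    out["m86"] = out["m86"] - kr86
    return BeamCycles(out)


def mass_bias(net: BeamCycles, c: IsotopeConstants = SR_CONSTANTS) -> float:
    """Exponential-law mass bias exponent from the Kr-corrected 88/86 beams.

    β = ln(R_canonical / R_measured) / ln(m88/m86); per-cycle values are
    combined by the median to stabilise low-beam cycles.
    """
    m86 = net.data["m86"].to_numpy()
    m88 = net.data["m88"].to_numpy()
    if np.any(m86 <= 0) or np.any(m88 <= 0):
        raise ValueError("non-positive 86 or 88 beam after correction")
    r_meas = m88 / m86
    beta = np.log(c.r88_86_canonical / r_meas) / math.log(c.m_sr88 / c.m_sr86)
    return float(np.median(beta))


def rb_correct(net: BeamCycles, beta: float,
               c: IsotopeConstants = SR_CONSTANTS) -> pd.Series:
    """87Sr beam after removing the 87Rb contribution.

    87Rb is predicted from the 85Rb monitor with the natural 87Rb/85Rb
    scaled to the *measured* (mass-biased) scale: since corrected ratios are
    measured·(m_num/m_den)^β, the measured Rb ratio is natural·(m87/m85)^(−β).
    """
    rb87 = net.data["m85"] * c.rb87_85 * (c.m_rb87 / c.m_rb85) ** (-beta)
    return net.data["m87"] - rb87


def reduce_spot(spot: SpotAnalysis, c: IsotopeConstants = SR_CONSTANTS,
                use_kr83: bool = False) -> ReducedSpot:
    """Run the per-spot correction chain up to the internally corrected
    87Sr/86Sr (bracketing normalisation is applied at session level)."""
    net = baseline_subtract(spot)
    net = kr_correct(net, c, use_kr83=use_kr83)
    flags: list[str] = []
    if (net.data["m84"] < 0).any() or (net.data["m86"] < 0).any():
        flags.append("negative_kr_corrected_beam")
    beta = mass_bias(net, c)
    sr87 = rb_correct(net, beta, c)
    if (sr87 < 0).any():
        flags.append("rb_overcorrection")
    m86 = net.data["m86"]
    f87 = (c.m_sr87 / c.m_sr86) ** beta
    r87_cycles = (sr87 / m86) * f87
    r84_cycles = (net.data["m84"] / m86) * (c.m_sr84 / c.m_sr86) ** beta
    rb86_cycles = ((net.data["m85"] * c.rb87_85) / m86) * (c.m_rb87 / c.m_sr86) ** beta
    n = len(r87_cycles)
    r87 = float(r87_cycles.mean())
    r87_2se = 2.0 * float(r87_cycles.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return ReducedSpot(
        spot_id=spot.spot_id,
        r87_86=r87,
        r87_86_2se=r87_2se,
        r84_86=float(r84_cycles.mean()),
        r87rb_86=float(rb86_cycles.mean()),
        beta=beta,
        role=spot.role,
        tooth=spot.tooth,
        transect=spot.transect,
        order=spot.order,
        flags=flags,
    )


def normalize_and_bracket(
    spots: Sequence[ReducedSpot],
    accepted_standard: float | None = None,
    c: IsotopeConstants = SR_CONSTANTS,
) -> list[ReducedSpot]:
    """Standard-sample-standard bracketing of internally corrected ratios.

    Bracketing-standard spots define a per-position correction factor
    accepted/measured, linearly interpolated in acquisition order between
    the nearest standards before and after each sample (session mean when a
    side is missing). Standards must exist in the session.
    """
    if accepted_standard is None:
        accepted_standard = c.seawater_87_86
    stds = [s for s in spots if s.role == "bracketing_standard"]
    if not stds:
        raise ValueError("no bracketing standards in session")
    std_orders = np.array([s.order for s in stds], dtype=float)
    std_factors = np.array([accepted_standard / s.r87_86 for s in stds])
    idx = np.argsort(std_orders)
    std_orders, std_factors = std_orders[idx], std_factors[idx]
    out = []
    for s in spots:
        if s.role == "bracketing_standard":
            factor = accepted_standard / s.r87_86
        else:
            factor = float(np.interp(s.order, std_orders, std_factors))
        out.append(
            ReducedSpot(
                spot_id=s.spot_id,
                r87_86=s.r87_86 * factor,
                r87_86_2se=s.r87_86_2se * factor,
                r84_86=s.r84_86,
                r87rb_86=s.r87rb_86,
                beta=s.beta,
                role=s.role,
                tooth=s.tooth,
                transect=s.transect,
                order=s.order,
                flags=list(s.flags),
            )
        )
    return out


def read_cycles(path) -> list[SpotAnalysis]:
    """Read a session cycle CSV: columns
    spot,role,tooth,transect,window,cycle,t_s,m82..m88 where window is
    'baseline' or 'ablation'."""
    df = pd.read_csv(path)
    spots = []
    for order, (spot_id, grp) in enumerate(df.groupby("spot", sort=False)):
        base = grp[grp["window"] == "baseline"]
        abl = grp[grp["window"] == "ablation"]
        role = str(grp["role"].iloc[0])
        spots.append(
            SpotAnalysis(
                spot_id=str(spot_id),
                baseline=BeamCycles(base.reset_index(drop=True)),
                ablation=BeamCycles(abl.reset_index(drop=True)),
                role=role,  # type: ignore[arg-type]
                tooth=str(grp["tooth"].iloc[0]) if "tooth" in grp else None,
                transect=str(grp["transect"].iloc[0]) if "transect" in grp else None,
                order=order,
            )
        )
    return spots


def reduce_session(
    spots: Sequence[SpotAnalysis],
    accepted_standard: float | None = None,
    c: IsotopeConstants = SR_CONSTANTS,
    use_kr83: bool = False,
    r84_86_tolerance: float = 0.002,
) -> list[ReducedSpot]:
    """Full-chain reduction of a session: per-spot corrections then
    bracketing. Spots whose corrected 84Sr/86Sr departs from the natural
    0.0565 by more than ``r84_86_tolerance`` are flagged."""
    reduced = [reduce_spot(s, c, use_kr83=use_kr83) for s in spots]
    reduced = normalize_and_bracket(reduced, accepted_standard, c)
    for r in reduced:
        if abs(r.r84_86 - c.r84_86_natural) > r84_86_tolerance:
            r.flags.append("r84_86_out_of_range")
    return reduced


def transect_summary(spots: Sequence[ReducedSpot]) -> list[TransectSummary]:
    """Mean ± 2SE of corrected 87Sr/86Sr per (tooth, transect) group.

    SE is sd/sqrt(n) of spot means; a single-spot group falls back to the
    spot's internal 2SE.
    """
    df = pd.DataFrame(
        {
            "tooth": [s.tooth for s in spots],
            "transect": [s.transect for s in spots],
            "r": [s.r87_86 for s in spots],
            "internal_2se": [s.r87_86_2se for s in spots],
        }
    )
    out = []
    for (tooth, tr), grp in df.groupby(["tooth", "transect"], sort=False):
        n = len(grp)
        mean = float(grp["r"].mean())
        if n > 1:
            two_se = 2.0 * float(grp["r"].std(ddof=1) / math.sqrt(n))
        else:
            two_se = float(grp["internal_2se"].iloc[0])
        out.append(TransectSummary(str(tooth), str(tr), mean, two_se, n))
    return out


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t-test: returns (t, Satterthwaite df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, float(len(a) + len(b) - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def kruskal_dunn(
    groups: dict[str, Sequence[float]],
    adjust: Literal["holm", "bonferroni", "none"] = "holm",
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal–Wallis H test with Dunn's pairwise post-hoc comparisons.

    Dunn's z statistics use the pooled rank variance with tie correction;
    pairwise p-values are adjusted by Holm's method by default. Returns
    (H, p, pairwise table).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    values = [np.asarray(groups[k], dtype=float) for k in names]
    all_vals = np.concatenate(values)
    if np.all(all_vals == all_vals[0]):
        pairs = pd.DataFrame(
            [(a, b, 0.0, 1.0, 1.0) for a, b in combinations(names, 2)],
            columns=["group_a", "group_b", "z", "p_raw", "p_adj"],
        )
        return 0.0, 1.0, pairs
    H, p = stats.kruskal(*values)
    n = len(all_vals)
    ranks = stats.rankdata(all_vals)
    # tie correction term for the rank variance
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    idx = np.cumsum([0] + [len(v) for v in values])
    mean_ranks = {
        k: float(np.mean(ranks[idx[i]: idx[i + 1]])) for i, k in enumerate(names)
    }
    rows = []
    for a, b in combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
        z = (mean_ranks[a] - mean_ranks[b]) / math.sqrt(var)
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, z, p_raw))
    pairs = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    if adjust == "none":
        pairs["p_adj"] = pairs["p_raw"]
    else:
        pairs["p_adj"] = multipletests(pairs["p_raw"], method=adjust)[1]
    return float(H), float(p), pairs
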