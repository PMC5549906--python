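"""Replicate aggregation and the nonparametric comparison protocol.

Each acquisition condition (angulation x direction) is scanned repeatedly;
the per-scan Rq values of one condition form a group. Groups are summarized
(mean, SD, IQR, CV, confidence interval) and compared with rank tests:
Kruskal-Wallis across all conditions, Mann-Whitney for each pair of
conditions and for whole-mesh vs central-ROI Rq. Pairwise outcomes are
encoded as significance letters: each condition is labeled a, b, c, ... in
a fixed order and lists the letters of every condition it differs from at
level alpha.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps

from .config import PipelineConfig
from .exceptions import (
    EmptyInputError,
    InsufficientReplicatesError,
    ParameterError,
    UndefinedStatisticError,
)
from .mesh import TriangleMesh
from .roughness import (
    BinCounts,
    RoughnessField,
    bin_proportions,
    central_roi,
    crop_border,
    rms,
    roughness_field,
)

#: Canonical condition order used for significance letters (a, b, c, d, e).
CANONICAL_CONDITION_ORDER = ("0", "30.1", "30.2", "45.1", "45.2")


@dataclass(frozen=True)
class AcquisitionCondition:
    """One acquisition setting: wafer angulation and tilt direction.

    Angulation 0 deg has no direction (the wafer faces the scanner);
    30 and 45 deg are tilted either away from (1) or toward (2) the
    scanner handle.
    """

    angulation: int
    direction: int | None = None
    scanner: str = ""

    def __post_init__(self) -> None:
        if self.angulation == 0:
            if self.direction is not None:
                raise ParameterError("angulation 0 has no direction")
        else:
            if self.direction not in (1, 2):
                raise ParameterError(
                    f"angulation {self.angulation} requires direction 1 or 2"
                )

    @property
    def label(self) -> str:
        if self.direction is None:
            return str(self.angulation)
        return f"{self.angulation}.{self.direction}"


def _cond_label(condition) -> str:
    return condition.label if isinstance(condition, AcquisitionCondition) else str(condition)


@dataclass(frozen=True)
class GroupSummary:
    """Summary of the replicate Rq values of one condition (all in um
    except CV, a percent). ``ci_half`` is the half-width of the
    two-sided (1 - alpha) confidence interval for the mean."""

    n: int
    mean: float
    sd: float
    iqr: float
    cv: float
    ci_half: float
    alpha: float = 0.05


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test."""

    method: str
    statistic: float
    pvalue: float
    group_sizes: tuple
    mode: str = ""


def group_summary(rq_values, alpha: float = 0.05, ci_method: str = "t",
                  strict: bool = True) -> GroupSummary:
    """Mean, sample SD, IQR, CV and CI half-width of replicate Rq values.

    SD uses the n-1 denominator; the IQR uses linearly interpolated
    percentiles; CV = 100 * SD / mean; the CI half-width is
    t(1 - alpha/2, n-1) * SD / sqrt(n) (or the normal quantile when
    ``ci_method='normal'``). With ``strict=False`` a single replicate
    yields NaN spread statistics instead of an error.
    """
    x = np.asarray(rq_values, dtype=float).ravel()
    if x.size == 0:
        raise EmptyInputError("group summary of no replicates")
    if (x < 0).any():
        raise ParameterError("Rq values must be non-negative")
    n = int(x.size)
    mean = float(x.mean())
    if n < 2:
        if strict:
            raise InsufficientReplicatesError(
                "SD/CV/CI require at least 2 replicates"
            )
        return GroupSummary(n, mean, math.nan, math.nan, math.nan, math.nan, alpha)
    sd = float(x.std(ddof=1))
    iqr = float(np.percentile(x, 75) - np.percentile(x, 25))
    if sd == 0.0:
        cv = 0.0
    elif mean == 0.0:
        cv = math.inf
    else:
        cv = 100.0 * sd / mean
    if ci_method == "t":
        q = float(sps.t.ppf(1 - alpha / 2, n - 1))
    elif ci_method == "normal":
        q = float(sps.norm.ppf(1 - alpha / 2))
    else:
        raise ParameterError("ci_method must be 't' or 'normal'")
    return GroupSummary(n, mean, sd, iqr, cv, q * sd / math.sqrt(n), alpha)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test across >=2 groups (tie-corrected mid-ranks,
    chi-square p with k-1 degrees of freedom)."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ParameterError("Kruskal-Wallis needs at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise EmptyInputError("Kruskal-Wallis groups must be non-empty")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ParameterError("Kruskal-Wallis needs at least 3 observations")
    if np.all(pooled == pooled[0]):
        raise UndefinedStatisticError(
            "all observations identical; tie correction degenerates"
        )
    h, p = sps.kruskal(*groups)
    return TestResult("kruskal-wallis", float(h), float(p),
                      tuple(g.size for g in groups))


def _u_statistic(ranks: np.ndarray, idx_a, n1: int) -> float:
    """U of the first sample from pooled mid-ranks and its index set."""
    return float(ranks[list(idx_a)].sum() - n1 * (n1 + 1) / 2)


def mann_whitney(a, b, mode: str = "auto",
                 max_arrangements: int = 400,
                 continuity: bool = True) -> TestResult:
    """Two-sided Mann-Whitney rank-sum test.

    ``mode='exact'`` enumerates every way of splitting the pooled sample
    (permutation-exact even with ties); it is allowed only when the number
    of arrangements C(n1+n2, n1) does not exceed ``max_arrangements``.
    ``mode='approx'`` uses the tie-corrected normal approximation (with a
    continuity correction unless ``continuity=False``). ``'auto'`` picks
    exact when it is affordable.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("Mann-Whitney samples must be non-empty")
    n1, n2 = int(a.size), int(b.size)
    total = math.comb(n1 + n2, n1)
    if mode == "auto":
        mode = "exact" if total <= max_arrangements else "approx"
    if mode not in ("exact", "approx"):
        raise ParameterError(f"unknown Mann-Whitney mode {mode!r}")

    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n1), n1)
    mid = n1 * n2 / 2.0

    if np.all(pooled == pooled[0]):
        # complete overlap: every arrangement gives U = n1*n2/2
        return TestResult("mann-whitney", u_obs, 1.0, (n1, n2), mode)

    if mode == "exact":
        if total > max_arrangements:
            raise ParameterError(
                f"exact mode would enumerate {total} arrangements "
                f"(> {max_arrangements})"
            )
        dev = abs(u_obs - mid)
        hits = sum(
            1
            for idx in itertools.combinations(range(n1 + n2), n1)
            if abs(_u_statistic(ranks, idx, n1) - mid) >= dev - 1e-12
        )
        return TestResult("mann-whitney", u_obs, hits / total, (n1, n2), "exact")

    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=continuity)
    return TestResult("mann-whitney", u_obs, float(res.pvalue), (n1, n2), "approx")


def percent_change(reference: float, value: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``."""
    if reference <= 0:
        raise ParameterError(f"reference must be positive, got {reference}")
    return 100.0 * (value - reference) / reference


def _ordered_labels(labels) -> list[str]:
    known = [l for l in CANONICAL_CONDITION_ORDER if l in labels]
    extra = sorted(l for l in labels if l not in CANONICAL_CONDITION_ORDER)
    return known + extra


def condition_letters(labels) -> dict[str, str]:
    """Assign a, b, c, ... to condition labels in the canonical order
    0, 30.1, 30.2, 45.1, 45.2 (unknown labels follow, sorted)."""
    ordered = _ordered_labels(list(labels))
    return {lab: chr(ord("a") + i) for i, lab in enumerate(ordered)}


def _holm_adjust(pvals: dict) -> dict:
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted, running = {}, 0.0
    for i, (key, p) in enumerate(items):
        running = max(running, min(1.0, (m - i) * p))
        adjusted[key] = running
    return adjusted


def significance_letters(groups, alpha: float = 0.05,
                         holm: bool = False) -> dict[str, set]:
    """Pairwise Mann-Whitney comparisons encoded as letter sets.

    ``groups`` maps condition (label or AcquisitionCondition) to replicate
    Rq values. Each condition's set contains the letters of every other
    condition it differs from at level ``alpha`` (symmetric by
    construction). Fewer than two conditions yields an empty mapping.
    """
    data = {_cond_label(k): np.asarray(v, dtype=float).ravel()
            for k, v in groups.items()}
    if len(data) < 2:
        return {}
    letters = condition_letters(data)
    pvals = {}
    for la, lb in itertools.combinations(_ordered_labels(data), 2):
        pvals[(la, lb)] = mann_whitney(data[la], data[lb]).pvalue
    if holm:
        pvals = _holm_adjust(pvals)
    out: dict[str, set] = {lab: set() for lab in data}
    for (la, lb), p in pvals.items():
        if p < alpha:
            out[la].add(letters[lb])
            out[lb].add(letters[la])
    return out


# ---------------------------------------------------------------------------
# Full pipeline: replicate meshes -> NoiseReport
# ---------------------------------------------------------------------------

@dataclass
class MeshEvaluation:
    """Per-scan pipeline products: roughness of the cropped whole mesh
    and of its central ROI."""

    whole_mesh: TriangleMesh
    whole_field: RoughnessField
    whole_rq: float
    whole_bins: BinCounts
    central_mesh: TriangleMesh
    central_field: RoughnessField
    central_rq: float
    central_bins: BinCounts


def evaluate_mesh(mesh: TriangleMesh, config: PipelineConfig | None = None) -> MeshEvaluation:
    """Run one scan through the pipeline: crop the wafer border, compute
    the roughness field and Rq on the whole (cropped) mesh, then repeat on
    the central ROI."""
    config = config or PipelineConfig()
    whole = crop_border(mesh, config.crop_margin)
    f_whole = roughness_field(whole, config.kernel_radius_mm)
    central = central_roi(whole, config.roi_fraction)
    f_central = roughness_field(central, config.kernel_radius_mm)
    return MeshEvaluation(
        whole_mesh=whole,
        whole_field=f_whole,
        whole_rq=rms(f_whole),
        whole_bins=bin_proportions(f_whole, config.bin_edges_um),
        central_mesh=central,
        central_field=f_central,
        central_rq=rms(f_central),
        central_bins=bin_proportions(f_central, config.bin_edges_um),
    )


@dataclass
class ConditionResult:
    """Aggregated result for one scanner x condition x region cell."""

    scanner: str
    condition_label: str
    region: str  # 'whole' or 'central'
    rq_values: np.ndarray
    summary: GroupSummary
    mean_bins: np.ndarray
    letters: set = field(default_factory=set)


@dataclass
class NoiseReport:
    """The table-shaped result of the protocol.

    ``results`` holds one entry per scanner x condition x region;
    ``pairwise`` the Mann-Whitney results among conditions (per scanner
    and region); ``whole_vs_central`` the per-condition region comparison;
    ``kruskal`` the across-conditions omnibus test per scanner and region
    (None when undefined, e.g. a noiseless pipeline where every Rq is 0).
    """

    results: list
    pairwise: dict
    whole_vs_central: dict
    kruskal: dict
    config: PipelineConfig
    bin_edges_um: tuple = field(default=None)

    def get(self, scanner: str, condition, region: str) -> ConditionResult:
        lab = _cond_label(condition)
        for r in self.results:
            if (r.scanner, r.condition_label, r.region) == (scanner, lab, region):
                return r
        raise KeyError((scanner, lab, region))

    def to_frame(self) -> pd.DataFrame:
        """One row per scanner x condition x region, Table-style columns."""
        rows = []
        for r in self.results:
            s = r.summary
            row = {
                "scanner": r.scanner,
                "condition": r.condition_label,
                "region": r.region,
                "n": s.n,
                "mean_rq_um": s.mean,
                "sd_um": s.sd,
                "iqr_um": s.iqr,
                "cv_pct": s.cv,
                "ci_half_um": s.ci_half,
                "letters": "".join(sorted(r.letters)),
            }
            edges = self.bin_edges_um or (5.0, 10.0, 20.0)
            names = [f"p_lt_{edges[0]:g}um"] + [
                f"p_{lo:g}_{hi:g}um" for lo, hi in zip(edges[:-1], edges[1:])
            ] + [f"p_gt_{edges[-1]:g}um"]
            for name, p in zip(names, r.mean_bins):
                row[name] = p
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        def tr(t):
            if t is None:
                return None
            return {"method": t.method, "statistic": t.statistic,
                    "pvalue": t.pvalue, "group_sizes": list(t.group_sizes)}

        return {
            "table": self.to_frame().to_dict(orient="records"),
            "pairwise": {
                f"{sc}|{region}|{la}_vs_{lb}": tr(t)
                for (sc, region, la, lb), t in self.pairwise.items()
            },
            "whole_vs_central": {
                f"{sc}|{lab}": tr(t) for (sc, lab), t in self.whole_vs_central.items()
            },
            "kruskal_wallis": {
                f"{sc}|{region}": tr(t) for (sc, region), t in self.kruskal.items()
            },
            "parameters": {
                "kernel_radius_mm": self.config.kernel_radius_mm,
                "crop_margin": self.config.crop_margin,
                "roi_fraction": self.config.roi_fraction,
                "bin_edges_um": list(self.config.bin_edges_um),
                "alpha": self.config.alpha,
                "ci_method": self.config.ci_method,
                "holm": self.config.holm,
            },
        }


def build_report(scans, config: PipelineConfig | None = None) -> NoiseReport:
    """Run the full protocol on replicate scans.

    Parameters
    ----------
    scans : mapping scanner label -> mapping condition -> list of meshes
        Conditions may be AcquisitionCondition objects or label strings
        ('0', '30.1', ...).
    config : PipelineConfig

    For every replicate the mesh is cropped, the roughness field computed
    and Rq / bin proportions recorded for the whole mesh and the central
    ROI. Per condition the replicates are summarized; conditions are
    compared pairwise (significance letters) and with Kruskal-Wallis, and
    the whole mesh is compared with the central ROI.
    """
    config = config or PipelineConfig()
    results: list[ConditionResult] = []
    pairwise: dict = {}
    whole_vs_central: dict = {}
    kruskal: dict = {}

    for scanner, cond_map in scans.items():
        rq_by_cond: dict[str, dict[str, list]] = {}
        bins_by_cond: dict[str, dict[str, list]] = {}
        for cond, meshes in cond_map.items():
            lab = _cond_label(cond)
            rq_by_cond[lab] = {"whole": [], "central": []}
            bins_by_cond[lab] = {"whole": [], "central": []}
            for mesh in meshes:
                ev = evaluate_mesh(mesh, config)
                rq_by_cond[lab]["whole"].append(ev.whole_rq)
                rq_by_cond[lab]["central"].append(ev.central_rq)
                bins_by_cond[lab]["whole"].append(ev.whole_bins.proportions)
                bins_by_cond[lab]["central"].append(ev.central_bins.proportions)

        labels = _ordered_labels(rq_by_cond)
        for region in ("whole", "central"):
            groups = {lab: rq_by_cond[lab][region] for lab in labels}
            letter_sets = significance_letters(groups, config.alpha, config.holm)
            for la, lb in itertools.combinations(labels, 2):
                pairwise[(scanner, region, la, lb)] = mann_whitney(
                    groups[la], groups[lb]
                )
            if len(labels) >= 2:
                try:
                    kruskal[(scanner, region)] = kruskal_wallis(
                        [groups[lab] for lab in labels]
                    )
                except UndefinedStatisticError:
                    kruskal[(scanner, region)] = None
            for lab in labels:
                vals = np.asarray(groups[lab], dtype=float)
                results.append(
                    ConditionResult(
                        scanner=scanner,
                        condition_label=lab,
                        region=region,
                        rq_values=vals,
                        summary=group_summary(
                            vals, config.alpha, config.ci_method, strict=False
                        ),
                        mean_bins=np.mean(bins_by_cond[lab][region], axis=0),
                        letters=letter_sets.get(lab, set()),
                    )
                )
        for lab in labels:
            whole_vs_central[(scanner, lab)] = mann_whitney(
                rq_by_cond[lab]["whole"], rq_by_cond[lab]["central"]
            )

    return NoiseReport(
        results=results,
        pairwise=pairwise,
        whole_vs_central=whole_vs_central,
        kruskal=kruskal,
        config=config,
        bin_edges_um=config.bin_edges_um,
    )
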