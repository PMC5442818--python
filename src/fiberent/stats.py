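"""Group comparisons for the split-mouth study design.

Three contrast families mirror the study's analysis:

* **side_within_timepoint** — treated (experimental) vs contralateral
  control side, paired within animal. The "ANOVA with a random animal
  effect" of a two-level paired design is exactly the paired t-test
  (F(1, n-1) = t^2), which is how the ``mixed_anova`` engine computes it;
  an exact within-animal sign-flip permutation test is provided as the
  distribution-free reference engine.
* **treatment_vs_baseline** — experimental side at each later timepoint
  vs the 0-week (day-of-surgery) group: independent animals, two-sample
  comparison, Bonferroni-adjusted across the timepoint family.
* **treatment_vs_noncolonized** — experimental side vs the healthy
  never-colonized reference group, same machinery.

All tests are two-sided; the significance level defaults to 0.05 with
star flags at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import stats as sps

from .fiber_entropy import PipelineConfig, fiber_entropy_pipeline
from .histomorphometry import (
    aggregate_study,
    cej_crest_distance,
    cementum_area,
    count_vessels,
)
from .preprocess import (
    NOT_COLONIZED,
    ValidationError,
    load_annotations,
    load_section,
)

logger = logging.getLogger(__name__)

CONTRASTS = ("side_within_timepoint", "treatment_vs_baseline", "treatment_vs_noncolonized")
ENGINES = ("mixed_anova", "permutation")
_EPS = 1e-12


@dataclass(frozen=True)
class ComparisonSpec:
    """What to compare and how."""

    measurement: str
    contrast: str = "side_within_timepoint"
    alpha: float = 0.05
    adjustment: str = "bonferroni"
    engine: str = "mixed_anova"
    n_permutations: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.contrast not in CONTRASTS:
            raise ValidationError(f"contrast must be one of {CONTRASTS}")
        if self.engine not in ENGINES:
            raise ValidationError(f"engine must be one of {ENGINES}")
        if self.adjustment not in ("bonferroni", "none"):
            raise ValidationError("adjustment must be 'bonferroni' or 'none'")


@dataclass(frozen=True)
class ComparisonResult:
    """One contrast's outcome (estimate = mean difference)."""

    measurement: str
    contrast: str
    timepoint: int | str
    estimate: float
    statistic: float
    p_value: float
    p_adjusted: float
    n: tuple[int, ...]
    engine: str

    def __post_init__(self) -> None:
        if not (self.p_adjusted >= self.p_value - _EPS and self.p_adjusted <= 1.0 + _EPS):
            raise ValidationError("p_adjusted must satisfy p <= p_adjusted <= 1")

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_adjusted < alpha

    @property
    def stars(self) -> str:
        p = self.p_adjusted
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return ""


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------

def _paired_t(diffs: np.ndarray) -> tuple[float, float]:
    n = diffs.size
    sd = diffs.std(ddof=1)
    mean = diffs.mean()
    if sd == 0.0:
        return (0.0, 1.0) if mean == 0.0 else (math.inf if mean > 0 else -math.inf, 0.0)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), float(p)


def _signflip_permutation(
    diffs: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Exact (full enumeration, n <= 20) or Monte-Carlo sign-flip test on
    within-animal differences; statistic is the mean difference."""
    n = diffs.size
    obs = abs(diffs.mean())
    if n <= 20:
        total = 1 << n
        count = 0
        bit_idx = np.arange(n, dtype=np.uint64)
        for start in range(0, total, 1 << 16):
            codes = np.arange(start, min(start + (1 << 16), total), dtype=np.uint64)
            signs = ((codes[:, None] >> bit_idx) & 1).astype(np.int8) * 2 - 1
            sums = signs @ diffs
            count += int(np.count_nonzero(np.abs(sums / n) >= obs - _EPS))
        return float(diffs.mean()), count / total
    signs = rng.choice((-1.0, 1.0), size=(n_permutations, n))
    sums = signs @ diffs
    # observed arrangement counts once among the draws (guards p > 0)
    count = 1 + int(np.count_nonzero(np.abs(sums / n) >= obs - _EPS))
    return float(diffs.mean()), count / (n_permutations + 1)


def _twosample_welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (math.inf, 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _twosample_permutation(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    max_exact: int = 20_000,
) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    n1 = a.size
    obs = abs(a.mean() - b.mean())
    n_exact = math.comb(pooled.size, n1)
    if n_exact <= max_exact:
        count = 0
        for idx in itertools.combinations(range(pooled.size), n1):
            sel = np.zeros(pooled.size, dtype=bool)
            sel[list(idx)] = True
            diff = pooled[sel].mean() - pooled[~sel].mean()
            if abs(diff) >= obs - _EPS:
                count += 1
        return float(a.mean() - b.mean()), count / n_exact
    count = 1
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if abs(perm[:n1].mean() - perm[n1:].mean()) >= obs - _EPS:
            count += 1
    return float(a.mean() - b.mean()), count / (n_permutations + 1)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _one_timepoint(defects: pd.DataFrame, timepoint: int | str | None) -> int | str:
    tps = defects["timepoint_weeks"].unique()
    if timepoint is None:
        if len(tps) != 1:
            raise ValidationError(
                "table spans several timepoints; pass timepoint= explicitly"
            )
        return tps[0]
    return timepoint


def side_comparison(
    defects: pd.DataFrame,
    spec: ComparisonSpec,
    timepoint: int | str | None = None,
) -> ComparisonResult:
    """Paired experimental-vs-control contrast at one timepoint.

    ``defects`` is a per-defect table (columns animal_id, side,
    timepoint_weeks, measurement, value). Animals missing either side are
    excluded with a warning; fewer than 3 complete pairs is an error.
    """
    tp = _one_timepoint(defects, timepoint)
    sub = defects[
        (defects["measurement"] == spec.measurement)
        & (defects["timepoint_weeks"] == tp)
    ]
    wide = sub.pivot_table(index="animal_id", columns="side", values="value")
    for col in ("experimental", "control"):
        if col not in wide.columns:
            wide[col] = np.nan
    unpaired = wide.index[wide[["experimental", "control"]].isna().any(axis=1)]
    if len(unpaired):
        logger.warning("excluding unpaired animal(s): %s", list(unpaired))
        wide = wide.drop(index=unpaired)
    if len(wide) < 3:
        raise ValidationError(
            f"side comparison needs >= 3 complete pairs, have {len(wide)}"
        )
    diffs = (wide["experimental"] - wide["control"]).to_numpy(dtype=float)
    if spec.engine == "mixed_anova":
        stat, p = _paired_t(diffs)
    else:
        rng = np.random.default_rng(spec.seed)
        stat, p = _signflip_permutation(diffs, spec.n_permutations, rng)
    return ComparisonResult(
        measurement=spec.measurement,
        contrast="side_within_timepoint",
        timepoint=tp,
        estimate=float(diffs.mean()),
        statistic=float(stat),
        p_value=float(p),
        p_adjusted=float(p),  # side contrasts are reported unadjusted
        n=(len(wide),),
        engine=spec.engine,
    )


def bonferroni_adjust(p_values: Sequence[float]) -> list[float]:
    """p_adj_i = min(1, m * p_i) with m = family size."""
    ps = [float(p) for p in p_values]
    if any(not (0.0 <= p <= 1.0) for p in ps):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(ps)
    return [min(1.0, m * p) for p in ps]


def reference_comparison(
    defects: pd.DataFrame,
    reference: str,
    spec: ComparisonSpec,
    timepoints: Sequence | None = None,
    side: str = "experimental",
) -> list[ComparisonResult]:
    """Experimental side vs a reference group (unpaired, independent mice).

    ``reference`` is "baseline_0wk" (the 0-week group) or "not_colonized"
    (the healthy reference). One contrast per timepoint in ``timepoints``
    (default: every later colonized timepoint present), Bonferroni-adjusted
    across that family when the spec asks for it.
    """
    if reference == "baseline_0wk":
        ref_tp: int | str = 0
        contrast = "treatment_vs_baseline"
    elif reference == "not_colonized":
        ref_tp = NOT_COLONIZED
        contrast = "treatment_vs_noncolonized"
    else:
        raise ValidationError(f"unknown reference {reference!r}")

    sub = defects[(defects["measurement"] == spec.measurement) & (defects["side"] == side)]
    ref_vals = sub.loc[sub["timepoint_weeks"] == ref_tp, "value"].to_numpy(dtype=float)
    if ref_vals.size == 0:
        raise ValidationError(f"reference group {reference!r} is empty")
    if timepoints is None:
        timepoints = sorted(
            tp
            for tp in sub["timepoint_weeks"].unique()
            if tp != ref_tp and tp != NOT_COLONIZED and not (ref_tp == 0 and tp == 0)
        )
    if not timepoints:
        raise ValidationError("no contrast timepoints available")

    results: list[ComparisonResult] = []
    rng = np.random.default_rng(spec.seed)
    for tp in timepoints:
        vals = sub.loc[sub["timepoint_weeks"] == tp, "value"].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValidationError(f"no data at timepoint {tp!r}")
        if spec.engine == "mixed_anova":
            stat, p = _twosample_welch(vals, ref_vals)
        else:
            stat, p = _twosample_permutation(vals, ref_vals, spec.n_permutations, rng)
        results.append(
            ComparisonResult(
                measurement=spec.measurement,
                contrast=contrast,
                timepoint=tp,
                estimate=float(vals.mean() - ref_vals.mean()),
                statistic=float(stat),
                p_value=float(p),
                p_adjusted=float(p),
                n=(vals.size, ref_vals.size),
                engine=spec.engine,
            )
        )
    if spec.adjustment == "bonferroni":
        adj = bonferroni_adjust([r.p_value for r in results])
        results = [replace(r, p_adjusted=a) for r, a in zip(results, adj)]
    return results


# ---------------------------------------------------------------------------
# study report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReportConfig:
    alpha: float = 0.05
    engine: str = "mixed_anova"
    adjustment: str = "bonferroni"
    measurements: tuple[str, ...] | None = None
    min_sections: int = 5
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int | None = None


@dataclass(eq=False)
class StudyReport:
    """Measurement tables and contrast results for one dataset."""

    defects: pd.DataFrame
    comparisons: pd.DataFrame
    summary: pd.DataFrame

    def flagged(self, alpha: float = 0.05) -> set[tuple[str, str, object]]:
        """(measurement, contrast, timepoint) triples significant at alpha."""
        sig = self.comparisons[self.comparisons["p_adjusted"] < alpha]
        return {
            (r.measurement, r.contrast, r.timepoint)
            for r in sig.itertuples()
        }


def _normalize_timepoint(v) -> int | str:
    if isinstance(v, str):
        return int(v) if v.strip().lstrip("-").isdigit() else v
    return int(v)


def measure_dataset(
    data_dir: str | Path, config: ReportConfig | None = None
) -> pd.DataFrame:
    """Run the full measurement pipeline over a dataset directory.

    Expects the layout written by the study generator (``metadata.csv``
    with image/annotation/mask paths). Returns the tidy per-section,
    per-replicate measurement table. Entropy results are memoized per
    (image, fiber-ROI geometry): the blinded replicates of a section share
    its raster, and the fiber analysis has no free-hand measurement step,
    so re-running it per replicate would reproduce the identical value.
    """
    cfg = config or ReportConfig()
    root = Path(data_dir)
    meta_path = root / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.csv under {root}: not a dataset directory")
    meta = pd.read_csv(meta_path)
    meta["timepoint_weeks"] = meta["timepoint_weeks"].map(_normalize_timepoint)

    tidy_rows: list[dict] = []
    entropy_cache: dict = {}
    mask_cache: dict = {}
    for row in meta.itertuples():
        ann = load_annotations(root / row.annotation_path)
        linkage = {
            "animal_id": row.animal_id,
            "side": row.side,
            "timepoint_weeks": row.timepoint_weeks,
            "section_index": int(row.section_index),
            "replicate_index": int(row.replicate_index),
        }
        fiber_rois = [
            r for r in ann.rois if r.compartment == "PDL" and r.fiber_class != "none"
        ]
        key = (
            row.image_path,
            tuple(
                (r.fiber_class, r.vertices.tobytes()) for r in fiber_rois
            ),
        )
        if key not in entropy_cache:
            section = load_section(root / row.image_path, linkage)
            entropy_cache[key] = fiber_entropy_pipeline(section, ann, cfg.pipeline)
        for res in entropy_cache[key]:
            tidy_rows.append(
                linkage
                | {"measurement": f"entropy_{res.fiber_class}", "value": res.entropy_bits}
            )
        dist = cej_crest_distance(ann)
        tidy_rows.append(linkage | {"measurement": "cej_crest_distance", "value": dist.px})
        mask_path = getattr(row, "mask_path", None)
        if isinstance(mask_path, str) and mask_path:
            if mask_path not in mask_cache:
                mask_cache[mask_path] = iio.imread(root / mask_path) > 0
            area = cementum_area(ann, mask_cache[mask_path])
            tidy_rows.append(linkage | {"measurement": "cementum_area", "value": area})
        for (comp, size), n in count_vessels(ann).items():
            name = f"vessel_count_{comp.lower()}" + (f"_{size}" if size != "all" else "")
            tidy_rows.append(linkage | {"measurement": name, "value": float(n)})
    return pd.DataFrame(tidy_rows)


def study_report(
    data_dir: str | Path,
    config: ReportConfig | None = None,
    out_dir: str | Path | None = None,
) -> StudyReport:
    """Measure a dataset and run every contrast family on it.

    Per measurement: the paired side contrast at each timepoint present,
    the Bonferroni-adjusted family of experimental-side contrasts against
    the 0-week baseline, and against the non-colonized reference when
    present. Writes ``defects.csv``, ``comparisons.csv``, ``summary.csv``
    and ``summary.md`` under ``out_dir`` when given.
    """
    cfg = config or ReportConfig()
    tidy = measure_dataset(data_dir, cfg)
    defects = aggregate_study(tidy, min_sections=cfg.min_sections)

    measurements = cfg.measurements or tuple(sorted(defects["measurement"].unique()))
    missing = set(measurements) - set(defects["measurement"].unique())
    if missing:
        raise ValidationError(f"measurements absent from dataset: {sorted(missing)}")

    timepoints = sorted(
        tp for tp in defects["timepoint_weeks"].unique() if tp != NOT_COLONIZED
    )
    has_nc = (defects["timepoint_weeks"] == NOT_COLONIZED).any()
    rows: list[ComparisonResult] = []
    for m in measurements:
        spec = ComparisonSpec(
            measurement=m,
            alpha=cfg.alpha,
            engine=cfg.engine,
            adjustment=cfg.adjustment,
            seed=cfg.seed,
        )
        side_tps = timepoints + ([NOT_COLONIZED] if has_nc else [])
        for tp in side_tps:
            rows.append(side_comparison(defects, spec, timepoint=tp))
        later = [tp for tp in timepoints if tp != 0]
        if 0 in timepoints and later:
            rows.extend(reference_comparison(defects, "baseline_0wk", spec, timepoints=later))
        if has_nc and timepoints:
            rows.extend(
                reference_comparison(defects, "not_colonized", spec, timepoints=timepoints)
            )

    comparisons = pd.DataFrame(
        [
            {
                "measurement": r.measurement,
                "contrast": r.contrast,
                "timepoint": r.timepoint,
                "estimate": r.estimate,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "n": "x".join(str(v) for v in r.n),
                "engine": r.engine,
                "significant": r.significant(cfg.alpha),
                "stars": r.stars,
            }
            for r in rows
        ]
    )
    summary = (
        defects[defects["measurement"].isin(measurements)]
        .groupby(["measurement", "timepoint_weeks", "side"])["value"]
        .agg(mean="mean", se=lambda v: v.std(ddof=1) / math.sqrt(len(v)), n="count")
        .reset_index()
    )
    report = StudyReport(defects=defects, comparisons=comparisons, summary=summary)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        defects.to_csv(out / "defects.csv", index=False)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        _write_summary_md(out / "summary.md", report, cfg)
    return report


def _write_summary_md(path: Path, report: StudyReport, cfg: ReportConfig) -> None:
    lines = [
        "# Split-mouth study report",
        "",
        f"Engine: {cfg.engine}; alpha = {cfg.alpha}; adjustment = {cfg.adjustment}",
        "",
        "## Defect means (mean +/- SE by side and timepoint)",
        "",
        report.summary.to_string(index=False),
        "",
        "## Contrasts",
        "",
        report.comparisons.to_string(index=False),
        "",
    ]
    path.write_text("\n".join(lines))
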