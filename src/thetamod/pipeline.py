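"""Orchestration: synth -> preprocess -> spectral -> metrics -> stats.

`run_all` drives a whole cohort from one RunConfig and writes every
intermediate table (QC, power, features) plus the statistics battery
outputs to the output directory, with the resolved config echoed for
provenance. Every stage is also callable on its own; no hidden state
passes between them beyond the files/objects documented here.

`verify_reported` recomputes every published statistic that is a pure
function of other printed numbers (p from r/n, F/df, t/df, z; partial
eta squared from F/df; variance explained from r) and checks agreement
at printed precision, propagating the rounding interval of the printed
statistic.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, spectral, stats
from .io import Montage, write_phenotypes
from .preprocess import ArtifactParams, run_preprocess
from .synth import SubjectBundle, SynthParams, build_montage, cohort_plan, iter_cohort

logger = logging.getLogger("thetamod")

__all__ = [
    "RunConfig",
    "subject_features",
    "cohort_tables",
    "cohort1_battery",
    "cohort2_battery",
    "cohort3_battery",
    "run_all",
    "verify_reported",
]


@dataclass
class RunConfig:
    """One document controlling a full run; serialized into the output dir."""

    seed: int = 0
    n_subjects: int = 36
    group_spec: dict[str, int] | None = None
    mode: str = "ln"  # 'ln' or 'linear' power for the percent-change metrics
    stats_plan: tuple = ("cohort1_battery",)
    synth: SynthParams = field(default_factory=SynthParams)
    artifacts: ArtifactParams = field(default_factory=ArtifactParams)

    def __post_init__(self) -> None:
        if self.mode not in ("ln", "linear"):
            raise ValueError(f"mode must be 'ln' or 'linear', got '{self.mode}'")
        known = {"cohort1_battery", "cohort2_battery", "cohort3_battery"}
        unknown = set(self.stats_plan) - known
        if unknown:
            raise ValueError(f"unknown stats plan entries {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["stats_plan"] = list(doc["stats_plan"])
        doc["synth"]["schedule"] = [list(s) for s in doc["synth"]["schedule"]]
        doc["synth"]["group_target_r"] = [list(s) for s in doc["synth"]["group_target_r"]]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "stats_plan" in doc:
            doc["stats_plan"] = tuple(doc["stats_plan"])
        synth = doc.pop("synth", {})
        synth["schedule"] = tuple(tuple(s) for s in synth.get("schedule",
                                                             SynthParams().schedule))
        synth["group_target_r"] = tuple(tuple(s) for s in synth.get("group_target_r", ()))
        art = doc.pop("artifacts", {})
        return cls(synth=SynthParams(**synth), artifacts=ArtifactParams(**art), **doc)


# ---------------------------------------------------------------------------
# Per-subject feature extraction
# ---------------------------------------------------------------------------

def subject_features(
    bundle: SubjectBundle,
    montage: Montage,
    config: RunConfig,
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Preprocess one subject and compute the derived indices.

    Returns (feature dict, power table, QC table); a subject whose
    primary index is undefined gets an ``exclusion_reason`` entry
    instead of metric fields.
    """
    sid = bundle.truth.subject_id if bundle.truth else bundle.recording.subject_id
    epochs, qc = run_preprocess(
        bundle.recording, bundle.events, bundle.attention, montage, config.artifacts
    )
    power = spectral.band_region_power(epochs, montage)
    row: dict = {"subject_id": sid, "group": bundle.truth.group if bundle.truth else ""}
    try:
        frontal_theta = spectral.frontal_power(power, band="theta")
        change, per_cond = metrics.within_video_change(frontal_theta, qc, mode=config.mode)
        row["pct_theta_frontal"] = change
        row["conditions_used"] = ",".join(sorted(per_cond))
        for cond, val in per_cond.items():
            row[f"pct_theta_{cond}"] = val
    except metrics.MetricUndefinedError as exc:
        return {"subject_id": sid, "exclusion_reason": str(exc)}, power, qc
    for name, table in (
        ("pct_theta_posterior",
         power[(power["region"] == "posterior") & (power["band"] == "theta")]),
        ("pct_alpha", spectral.frontal_power(power, band="upper_alpha")),
    ):
        try:
            row[name], _ = metrics.within_video_change(table, qc, mode=config.mode)
        except metrics.MetricUndefinedError:
            row[name] = np.nan
    try:
        row["pct_attended"] = metrics.attended_proportion_change(qc)
    except metrics.MetricUndefinedError:
        row["pct_attended"] = np.nan
    for cond in ("social", "nonsocial"):
        try:
            row[f"rep_change_{cond}"] = metrics.between_repetition_change(
                frontal_theta, qc, cond, mode=config.mode
            )
        except metrics.MetricUndefinedError:
            row[f"rep_change_{cond}"] = np.nan
        try:
            row[f"baseline_theta_{cond}"] = metrics.baseline_power(
                frontal_theta, cond, mode=config.mode
            )
        except metrics.MetricUndefinedError:
            row[f"baseline_theta_{cond}"] = np.nan
    return row, power, qc


def cohort_tables(
    bundles,
    montage: Montage,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Feature, power and QC tables for a whole cohort.

    ``bundles`` may be any iterable of SubjectBundle — pass
    ``synth.iter_cohort(...)`` for large cohorts so recordings are
    processed and released one at a time.
    """
    rows, powers, qcs = [], [], []
    for b in bundles:
        row, power, qc = subject_features(b, montage, config)
        rows.append(row)
        powers.append(power)
        qcs.append(qc)
    features = metrics.feature_table(rows)
    if len(features):
        features = features.set_index("subject_id", drop=False)
    powers = [p for p in powers if len(p)] or powers[:1]
    return features, pd.concat(powers, ignore_index=True), pd.concat(qcs, ignore_index=True)


# ---------------------------------------------------------------------------
# Statistics batteries
# ---------------------------------------------------------------------------

def _merged(features: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.DataFrame:
    return features.join(phenotypes.drop(columns=["subject_id", "group"],
                                         errors="ignore"), how="inner")


def cohort1_battery(
    features: pd.DataFrame,
    power: pd.DataFrame,
    phenotypes: pd.DataFrame,
    score_cols: tuple[str, str] = ("nonverbal_t_12m", "verbal_t_12m"),
) -> dict:
    """The discovery-cohort battery.

    2x2x2 within-subject ANOVA on frontal ln theta (condition x half x
    region, first presentations); one-sample t on the attended-proportion
    change; correlations of the theta index with concurrent scores plus
    the posterior/alpha/attention specificity controls; the Steiger
    comparison of the theta and alpha correlations; and the
    repetition-learning partial correlations (baseline theta partialled).
    """
    out: dict = {}
    anova_df = power[
        (power["band"] == "theta")
        & (power["repetition"] == 1)
        & power["region"].isin(["frontal_left", "frontal_right"])
    ].rename(columns={"subject": "subject", "ln_power": "value"})
    anova_df = anova_df.assign(region=anova_df["region"].map(
        {"frontal_left": "left", "frontal_right": "right"}))
    try:
        out["anova"] = stats.rm_anova_2x2x2(anova_df)
        cell_means = anova_df.groupby(["condition", "half", "region"])["value"].mean()
        out["cell_means"] = cell_means
    except (stats.InsufficientDataError, ValueError) as exc:
        logger.warning("cohort1 ANOVA skipped: %s", exc)

    data = _merged(features, phenotypes)
    if "pct_attended" in data:
        try:
            t, df, p = stats.one_sample_t(data["pct_attended"])
            out["attended_t"] = {"t": t, "df": df, "p": p,
                                 "mean": float(data["pct_attended"].mean()),
                                 "sd": float(data["pct_attended"].std(ddof=1))}
        except (stats.InsufficientDataError, stats.DegenerateInputError) as exc:
            logger.warning("attended-proportion t skipped: %s", exc)

    corrs = {}
    for score in score_cols:
        if score not in data:
            continue
        for feat in ("pct_theta_frontal", "pct_theta_posterior", "pct_alpha",
                     "pct_attended"):
            if feat not in data:
                continue
            try:
                corrs[(feat, score)] = stats.pearson(data[feat], data[score])
            except (stats.InsufficientDataError, stats.DegenerateInputError) as exc:
                logger.warning("corr(%s, %s) skipped: %s", feat, score, exc)
        theta_key, alpha_key = ("pct_theta_frontal", score), ("pct_alpha", score)
        if theta_key in corrs and alpha_key in corrs:
            complete = data[["pct_theta_frontal", "pct_alpha", score]].dropna()
            if len(complete) >= 4:
                r12 = stats.pearson(complete["pct_theta_frontal"],
                                    complete["pct_alpha"]).r
                out[f"steiger_{score}"] = stats.steiger_dependent(
                    corrs[theta_key].r, corrs[alpha_key].r, r12, len(complete)
                )
    out["correlations"] = corrs

    partials = {}
    for within_cond in ("social", "nonsocial"):
        for rep_cond in ("social", "nonsocial"):
            cols = [f"pct_theta_{within_cond}", f"rep_change_{rep_cond}",
                    f"baseline_theta_{within_cond}"]
            if any(c not in features for c in cols):
                continue
            sub = features.dropna(subset=cols)
            if len(sub) < 5:
                continue
            try:
                partials[(within_cond, rep_cond)] = stats.partial_corr(
                    sub[cols[0]], sub[cols[1]], sub[cols[2]],
                    names=[cols[2]],
                )
            except (stats.InsufficientDataError, stats.DegenerateInputError) as exc:
                logger.warning("partial corr %s/%s skipped: %s",
                               within_cond, rep_cond, exc)
    out["repetition_partials"] = partials
    return out


def cohort2_battery(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    score_cols: tuple[str, ...] = ("nonverbal_t_12m", "verbal_t_12m"),
) -> dict:
    """Correlation-only battery for a longitudinal follow-up cohort."""
    data = _merged(features, phenotypes)
    corrs = {}
    for score in score_cols:
        if score not in data:
            continue
        for feat in ("pct_theta_frontal", "pct_theta_posterior", "pct_alpha",
                     "pct_attended"):
            if feat not in data:
                continue
            try:
                corrs[(feat, score)] = stats.pearson(data[feat], data[score])
            except (stats.InsufficientDataError, stats.DegenerateInputError) as exc:
                logger.warning("corr(%s, %s) skipped: %s", feat, score, exc)
    return {"correlations": corrs, "n": len(data)}


def cohort3_battery(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    score_col: str = "nonverbal_t_12m",
    covariate_col: str | None = None,
) -> dict:
    """Group ANCOVA: score ~ theta + group + theta:group (+ covariate)."""
    data = _merged(features, phenotypes)
    cols = ["pct_theta_frontal", score_col, "group"]
    if covariate_col:
        cols.append(covariate_col)
    data = data.dropna(subset=[c for c in cols if c in data])
    out: dict = {"n": len(data)}
    try:
        out["ancova"] = stats.ancova_group(
            data[score_col], data["pct_theta_frontal"], data["group"],
            covariate=data[covariate_col] if covariate_col else None,
        )
    except (stats.InsufficientDataError, stats.DegenerateInputError) as exc:
        logger.warning("cohort3 ANCOVA skipped: %s", exc)
    return out


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _format_report(results: dict) -> str:
    lines = []
    for battery, res in results.items():
        lines.append(f"== {battery} ==")
        if "anova" in res:
            lines.append(res["anova"].table.to_string(index=False,
                                                      float_format="%.4g"))
        if "attended_t" in res:
            a = res["attended_t"]
            lines.append(
                f"attended-proportion change: M = {a['mean']:.3f}, SD = {a['sd']:.3f}, "
                f"t({a['df']}) = {a['t']:.2f}, p = {a['p']:.3g}"
            )
        for key, val in res.get("correlations", {}).items():
            lines.append(f"corr {key[0]} ~ {key[1]}: {val}")
        for key in res:
            if key.startswith("steiger_"):
                s = res[key]
                lines.append(
                    f"{key}: Z = {s.z:.2f}, one-sided p = {s.p_one_sided:.3g}"
                )
        for key, val in res.get("repetition_partials", {}).items():
            lines.append(f"partial within-{key[0]} ~ rep-{key[1]}: {val}")
        if "ancova" in res:
            lines.append(res["ancova"].table.to_string(index=False,
                                                       float_format="%.4g"))
            for g, cr in res["ancova"].extra.get("group_r", {}).items():
                lines.append(f"  within-{g}: {cr}")
        lines.append("")
    return "\n".join(lines)


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Synthesize, preprocess, extract features and run the planned stats.

    Deterministic given ``config.seed``; writes features.csv, power.csv,
    qc_report.csv, phenotypes.csv, the battery CSVs, report.txt and the
    resolved config.yaml into ``outdir``. Fails hard only when no subject
    survives QC; per-subject exclusions are warnings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    fh = logging.FileHandler(outdir / "run.log")
    fh.setLevel(logging.INFO)
    logger.addHandler(fh)
    try:
        truths, phenotypes, _ = cohort_plan(
            config.synth, config.n_subjects, group_spec=config.group_spec,
            seed=config.seed,
        )
        bundles = iter_cohort(
            config.synth, config.n_subjects, group_spec=config.group_spec,
            seed=config.seed,
        )
        montage = build_montage(config.synth.n_channels)
        features, power, qc = cohort_tables(bundles, montage, config)
        if not len(features):
            qc.to_csv(outdir / "qc_report.csv", index=False)
            raise RuntimeError(
                "no subject survived QC; see qc_report.csv for per-half counts"
            )
        features.to_csv(outdir / "features.csv", index=False)
        power.to_csv(outdir / "power.csv", index=False)
        with open(outdir / "qc_report.csv", "w") as f:
            f.write(f"# thresholds: {dataclasses.asdict(config.artifacts)}\n")
            qc.to_csv(f, index=False)
        write_phenotypes(phenotypes, outdir / "phenotypes.csv")

        results: dict = {}
        if "cohort1_battery" in config.stats_plan:
            results["cohort1_battery"] = cohort1_battery(features, power, phenotypes)
        if "cohort2_battery" in config.stats_plan:
            results["cohort2_battery"] = cohort2_battery(features, phenotypes)
        if "cohort3_battery" in config.stats_plan:
            results["cohort3_battery"] = cohort3_battery(features, phenotypes)
        report = _format_report(results)
        (outdir / "report.txt").write_text(report)
        for name, res in results.items():
            if "anova" in res:
                res["anova"].table.to_csv(outdir / f"{name}_anova.csv", index=False)
            if "ancova" in res:
                res["ancova"].table.to_csv(outdir / f"{name}_ancova.csv", index=False)
            if res.get("correlations"):
                pd.DataFrame(
                    [
                        dict(feature=k[0], score=k[1], r=v.r, n=v.n, df=v.df,
                             t=v.t, p=v.p)
                        for k, v in res["correlations"].items()
                    ]
                ).to_csv(outdir / f"{name}_correlations.csv", index=False)
        return {"features": features, "power": power, "qc": qc,
                "phenotypes": phenotypes, "truths": truths, "results": results}
    finally:
        logger.removeHandler(fh)
        fh.close()


# ---------------------------------------------------------------------------
# Printed-statistics verification
# ---------------------------------------------------------------------------

def _printed_ulp(printed: str) -> float:
    s = str(printed).strip()
    return 0.5 * 10 ** -(len(s.split(".")[1]) if "." in s else 0)


def _recompute_interval(row: pd.Series) -> tuple[float, float, float]:
    """(lo, mid, hi) of the recomputed quantity over the printed-statistic
    rounding interval."""
    stat = float(row["statistic"])
    ulp = _printed_ulp(row["statistic_str"])
    lo_s, hi_s = stat - ulp, stat + ulp
    kind = row["kind"]
    if kind == "pearson_p":
        n = int(row["n"])

        def p_of(r: float) -> float:
            r = min(abs(r), 1 - 1e-12)
            t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
            return stats.p_from_statistic("t", t, n - 2)

        vals = [p_of(lo_s), p_of(stat), p_of(hi_s)]
    elif kind == "f_p":
        dfp = (float(row["df1"]), float(row["df2"]))
        vals = [stats.p_from_statistic("F", max(s, 0.0), dfp) for s in (lo_s, stat, hi_s)]
    elif kind == "t_p":
        d = float(row["df1"])
        vals = [stats.p_from_statistic("t", abs(s), d) for s in (lo_s, stat, hi_s)]
    elif kind == "z_p":
        vals = [stats.p_from_statistic("z", s, None, sided="one")
                for s in (lo_s, stat, hi_s)]
    elif kind == "eta_f":
        d1, d2 = float(row["df1"]), float(row["df2"])
        vals = [s * d1 / (s * d1 + d2) for s in (lo_s, stat, hi_s)]
    elif kind == "var_from_r":
        vals = [100.0 * s * s for s in (lo_s, stat, hi_s)]
    else:
        raise ValueError(f"unknown verification kind '{kind}'")
    return min(vals), vals[1], max(vals)


def verify_reported(path: str | Path | None = None) -> pd.DataFrame:
    """Recompute every derivable printed statistic and compare.

    A row passes when the interval of recomputed values (statistic read
    at +/- half its printed precision) overlaps the printed value at
    +/- half *its* printed precision; ``le`` rows ("p < x") pass when
    the whole recomputed interval sits below the bound.
    """
    if path is None:
        src = importlib.resources.files("thetamod").joinpath("data/reported_stats.csv")
        table = pd.read_csv(src, dtype={"printed": str, "statistic": str})
    else:
        table = pd.read_csv(path, dtype={"printed": str, "statistic": str})
    rows = []
    for _, row in table.iterrows():
        row = row.copy()
        row["statistic_str"] = row["statistic"]
        row["statistic"] = float(row["statistic"])
        lo, mid, hi = _recompute_interval(row)
        printed = float(row["printed"])
        p_ulp = _printed_ulp(row["printed"])
        if row["cmp"] == "le":
            passed = hi <= printed
        else:
            passed = (lo <= printed + p_ulp) and (hi >= printed - p_ulp)
        rows.append(
            dict(
                row_id=row["row_id"],
                kind=row["kind"],
                statistic=row["statistic"],
                printed=printed,
                recomputed=mid,
                recomputed_lo=lo,
                recomputed_hi=hi,
                cmp=row["cmp"],
                derivable=int(row["derivable"]),
                passed=bool(passed),
                label=row["label"],
            )
        )
    out = pd.DataFrame(rows)
    n_ok = int(out.loc[out["derivable"] == 1, "passed"].sum())
    n_all = int((out["derivable"] == 1).sum())
    logger.info("verify_reported: %d/%d derivable rows pass", n_ok, n_all)
    return out
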