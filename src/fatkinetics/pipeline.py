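"""End-to-end analysis pipeline: simulate -> quantify -> fit -> test -> associate -> report.

Each stage is a plain function over tidy tables so the numbered analysis
drivers, the command-line interface and the tests all share one code path.
A full run writes its configuration copy, every stage table as CSV, a
Markdown summary and a log with SHA-256 checksums of each artifact; the
report files are byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import ANALYTES, COMPARTMENTS, CohortConfig, generate_cohort
from .kinetics import PopulationFit, decay_constants, fit_population
from .phantom import PhantomSpec, make_phantom
from .quantify import mask_volume, mean_fat_fraction
from .stats import (
    baseline_values,
    compare_decay_constants,
    comparisons_vs_baseline,
    delta_from_baseline,
    homa_ir,
    ols_simple,
    percent_decline,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "run_all",
    "with_homa",
    "fit_stage",
    "phantom_stage",
    "summary_stage",
    "baseline_stage",
    "associate_stage",
]

logger = logging.getLogger(__name__)

#: compartments whose blood-parameter associations are tabulated
ASSOCIATION_COMPARTMENTS = ("lf_percent", "vat", "sat")
ASSOCIATION_RESPONSES = tuple(ANALYTES) + ("homa",)


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    outdir: Path = Path("run")
    seed: int | None = None  # overrides cohort.rng_seed when given
    figures: bool = False

    def resolved_cohort(self) -> CohortConfig:
        if self.seed is None:
            return self.cohort
        return dataclasses.replace(self.cohort, rng_seed=int(self.seed))


@dataclass
class RunReport:
    """Tables produced by one run, keyed as written to disk."""

    tables: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)  # name -> sha256
    seed: int = 0
    version: str = __version__


def with_homa(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add the row-wise HOMA-IR column (NaN where glucose/insulin missing)."""
    out = cohort.copy()
    g = out["glucose"].to_numpy(dtype=float)
    i = out["insulin"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out["homa"] = g * i / 22.5
    return out


def phantom_stage(spec: PhantomSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Build one phantom and quantify it against its own ground truth."""
    labels, ff, truth = make_phantom(spec, rng)
    rows = []
    for name in ("liver", "sat", "vat"):
        vol = mask_volume(labels, name)
        row = {
            "label": name,
            "volume_cm3": vol,
            "truth_cm3": truth.volumes_cm3[name],
        }
        if name in truth.mean_ff:
            row["mean_ff_percent"] = mean_fat_fraction(ff, labels, name)
            row["truth_ff_percent"] = truth.mean_ff[name]
        rows.append(row)
    return pd.DataFrame(rows)


def summary_stage(cohort: pd.DataFrame) -> pd.DataFrame:
    """Trajectory summary: cohort mean +/- SEM per visit month.

    Includes the change in BMI from baseline and the mean per-subject
    percent decline in liver fat (mean of ratios, not ratio of means).
    """
    cohort = with_homa(cohort)
    months = sorted(cohort["time"].unique())
    fields = ["bmi", "lf_percent", "tlv", "vat", "sat", "glucose", "insulin", "homa",
              "total_chol", "hdl", "ldl", "triglycerides"]
    rows = []
    lf_base = baseline_values(cohort, "lf_percent")
    bmi_base = baseline_values(cohort, "bmi")
    for m in months:
        sub = cohort[cohort["time"] == m]
        row: dict = {"time": m, "n": sub["subject_id"].nunique()}
        for f in fields:
            vals = sub.groupby("subject_id")[f].mean().dropna()
            row[f"{f}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{f}_sem"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
        if m > 0:
            lf_now = sub.groupby("subject_id")["lf_percent"].mean()
            joined = pd.concat([lf_base, lf_now], axis=1, keys=["b", "v"]).dropna()
            declines = percent_decline(joined["b"].to_numpy(), joined["v"].to_numpy())
            row["lf_decline_mean"] = float(np.mean(declines))
            bmi_now = sub.groupby("subject_id")["bmi"].mean()
            joined_b = pd.concat([bmi_base, bmi_now], axis=1, keys=["b", "v"]).dropna()
            row["delta_bmi_mean"] = float((joined_b["v"] - joined_b["b"]).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def fit_stage(cohort: pd.DataFrame) -> tuple[dict, pd.DataFrame]:
    """Two-stage population fits per compartment; Table of coefficients.

    The per-coefficient p-value is a two-sided t-test of the fixed effect
    against zero on n-1 degrees of freedom.
    """
    from scipy import stats as sps

    popfits: dict[str, PopulationFit] = {}
    rows = []
    for comp in COMPARTMENTS:
        pf = fit_population(cohort, comp)
        popfits[comp] = pf
        est = pf.fixed_effects.as_array()
        for name, e, se in zip(("A", "B", "A1"), est, pf.se):
            tstat = e / se if se > 0 else np.inf
            p = 2 * sps.t.sf(abs(tstat), pf.n_subjects - 1) if se > 0 else 0.0
            rows.append(
                {
                    "compartment": comp,
                    "coefficient": name,
                    "estimate": e,
                    "se": se,
                    "p": p,
                    "n_subjects": pf.n_subjects,
                }
            )
    return popfits, pd.DataFrame(rows)


def baseline_stage(cohort: pd.DataFrame) -> pd.DataFrame:
    """Blood-parameter comparisons vs baseline, Bonferroni per parameter."""
    cohort = with_homa(cohort)
    rows = []
    for param in ASSOCIATION_RESPONSES:
        res = comparisons_vs_baseline(cohort, param)
        for _, r in res.iterrows():
            rows.append({"parameter": param, **r.to_dict()})
    return pd.DataFrame(rows)


def associate_stage(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint linear associations of blood parameters with compartments.

    Mode ``absolute`` regresses the analyte on the compartment value at each
    month; mode ``delta`` regresses the change from the preoperative value
    on the compartment's change.  P-values are unadjusted.
    """
    cohort = with_homa(cohort)
    rows = []
    for comp in ASSOCIATION_COMPARTMENTS:
        deltas_comp = delta_from_baseline(cohort, comp)
        for resp in ASSOCIATION_RESPONSES:
            for m in sorted(cohort["time"].unique()):
                sub = cohort[cohort["time"] == m].dropna(subset=[comp, resp])
                sub = sub.groupby("subject_id")[[comp, resp]].mean()
                if len(sub) >= 3 and sub[comp].nunique() > 1:
                    res = ols_simple(sub[comp], sub[resp])
                    rows.append(
                        {
                            "compartment": comp,
                            "response": resp,
                            "time": m,
                            "mode": "absolute",
                            "slope": res.slope,
                            "se": res.se,
                            "p": res.p,
                            "n": res.n,
                        }
                    )
            deltas_resp = delta_from_baseline(cohort, resp)
            merged = deltas_comp.merge(
                deltas_resp, on=["subject_id", "time"], suffixes=("_comp", "_resp")
            )
            for m, grp in merged.groupby("time"):
                if len(grp) >= 3 and grp["delta_comp"].nunique() > 1:
                    res = ols_simple(grp["delta_comp"], grp["delta_resp"])
                    rows.append(
                        {
                            "compartment": comp,
                            "response": resp,
                            "time": m,
                            "mode": "delta",
                            "slope": res.slope,
                            "se": res.se,
                            "p": res.p,
                            "n": res.n,
                        }
                    )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _trajectory_figure(cohort: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, comp in zip(axes.ravel(), COMPARTMENTS):
        agg = cohort.groupby("time")[comp].agg(["mean", "sem"])
        ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], fmt="o-")
        ax.set_title(comp)
        ax.set_xlabel("months after surgery")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage, write artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_cfg = config.resolved_cohort()
    seed = cohort_cfg.rng_seed
    report = RunReport(seed=seed)

    log_lines = [
        f"# pipeline run, fatkinetics {__version__}",
        f"started: {datetime.now(timezone.utc).isoformat()}",
        f"seed: {seed}",
    ]

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        _write_csv(df, path)
        report.tables[name] = df
        report.files[f"{name}.csv"] = _sha256(path)
        log_lines.append(f"stage={name} file={path.name} sha256={report.files[f'{name}.csv']}")

    try:
        cohort_cfg.to_yaml(outdir / "config.yaml")
        report.files["config.yaml"] = _sha256(outdir / "config.yaml")

        cohort = generate_cohort(cohort_cfg)
        emit("cohort", cohort)

        rng_ph = np.random.default_rng((seed + 1) % 2**31)
        emit("phantom_volumes", phantom_stage(config.phantom, rng_ph))

        emit("trajectory_summary", summary_stage(cohort))

        popfits, coeffs = fit_stage(cohort)
        emit("kinetic_coefficients", coeffs)

        dtable = decay_constants(popfits)
        emit("decay_constants", dtable.reset_index())
        emit("decay_comparison", compare_decay_constants(dtable))

        emit("blood_vs_baseline", baseline_stage(cohort))
        emit("associations", associate_stage(cohort))

        if config.figures:
            _trajectory_figure(cohort, outdir / "trajectories.png")
    except Exception as exc:
        stage = len(report.tables)
        logger.error("pipeline failed after %d stages: %s", stage, exc)
        raise

    _write_report_md(report, outdir)
    report.files["report.md"] = _sha256(outdir / "report.md")
    log_lines.append(f"finished: {datetime.now(timezone.utc).isoformat()}")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return report


def _write_report_md(report: RunReport, outdir: Path) -> None:
    lines = [
        "# Fat-kinetics pipeline report",
        "",
        f"- package version: {report.version}",
        f"- seed: {report.seed}",
        "",
        "## Decay constants (per compartment, mean of per-subject -B)",
        "",
    ]
    coeffs = report.tables["kinetic_coefficients"]
    bb = coeffs[coeffs["coefficient"] == "B"]
    for _, r in bb.iterrows():
        lines.append(
            f"- {r['compartment']}: decay constant {-r['estimate']:.4f}"
            f" (fixed effect B = {r['estimate']:.4f} +/- {r['se']:.4f})"
        )
    lines += ["", "## Pairwise decay-constant comparisons (paired Wilcoxon)", ""]
    for _, r in report.tables["decay_comparison"].iterrows():
        lines.append(
            f"- {r['compartment_1']} vs {r['compartment_2']}:"
            f" n={r['n_pairs']}, W={r['w']:.1f}, p={r['p']:.3g} ({r['method']})"
        )
    lines += ["", "## Artifacts", ""]
    for name, digest in sorted(report.files.items()):
        lines.append(f"- {name}: sha256 {digest[:16]}...")
    (outdir / "report.md").write_text("\n".join(lines) + "\n", encoding="utf-8")
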