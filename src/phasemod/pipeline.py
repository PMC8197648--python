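"""End-to-end analysis pipeline: scores -> harmonic fits -> circular
statistics -> sham comparison -> report.

`run_pipeline` takes a validated `RunConfig` (either a simulation preset
or a path to a scores CSV), executes per-source: centering, OLS and
robust harmonic fits with FDR correction, amplitude/phase extraction,
the bootstrap r^2 comparison, the best-phase-aligned refits, and the
circular analysis of per-subject best phases; then the amplitude
comparison between sources and the one-way ANOVA against sham.  Every
stochastic step receives an explicit seed derived from the config seed,
so a config hash plus seed fully determines the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circular as circ
from . import phase_model as pm
from . import synthgen
from .errors import ConfigurationError, InvalidInputError

logger = logging.getLogger("phasemod")

SCHEMA_COLUMNS = list(pm.SCORE_COLUMNS)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    scores_csv: str | None = None        # mutually exclusive with preset
    preset: str | None = "study"         # "study" emulates the experimental design
    sources: tuple[str, ...] = ("target", "distractor")
    methods: tuple[str, ...] = ("ols", "robust")
    n_boot: int = 10_000
    seed: int = 0
    out_dir: str | None = None
    make_figures: bool = False
    bootstrap_unit: str = "subject"
    jitter_halfwidth_deg: float = 0.0

    def __post_init__(self):
        if (self.scores_csv is None) == (self.preset is None):
            raise ConfigurationError("give exactly one of scores_csv or preset")
        if self.preset is not None and self.preset != "study":
            raise ConfigurationError(f"unknown preset {self.preset!r}")
        bad = set(self.sources) - {"target", "distractor"}
        if bad:
            raise ConfigurationError(f"cannot analyze sources {sorted(bad)}")
        bad = set(self.methods) - {"ols", "robust"}
        if bad:
            raise ConfigurationError(f"unknown methods {sorted(bad)}")
        if self.n_boot < 2:
            raise ConfigurationError("n_boot must be at least 2")

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (where the report is
        written does not change what is computed)."""
        payload = asdict(self)
        payload.pop("out_dir")
        payload.pop("make_figures")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StudyReport:
    """All pipeline outputs, traceable to config hash and seeds."""

    config_hash: str
    seed: int
    fits: dict = field(default_factory=dict)           # (source, method, aligned) tables
    bootstrap: dict = field(default_factory=dict)      # per source
    circular: dict = field(default_factory=dict)       # per source
    amplitude_comparison: dict | None = None
    sham_anova: dict | None = None
    provenance: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON run configuration."""
    import yaml

    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path} did not parse to a mapping")
    for key in ("sources", "methods"):
        if key in data:
            data[key] = tuple(data[key])
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigurationError(f"bad config keys: {exc}") from exc


# ---------------------------------------------------------------------------
# scores I/O
# ---------------------------------------------------------------------------

def read_scores(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-form scores CSV.

    Schema: subject_id, source {target|distractor|sham}, phase_deg (empty
    for sham), n_keywords, n_correct.  Violations are reported with row
    numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InvalidInputError(
            f"{path}: empty scores file; expected columns {SCHEMA_COLUMNS}"
        ) from None
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(
            f"{path}: missing columns {missing}; expected {SCHEMA_COLUMNS}"
        )
    return pm.validate_scores(df)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SCHEMA_COLUMNS if c in scores.columns]
    scores[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def _fit_record(fit: pm.HarmonicFit) -> dict:
    return {
        "coefficients": {
            name: {
                "estimate": float(row["estimate"]),
                "ci_low": float(row["ci_low"]),
                "ci_high": float(row["ci_high"]),
                "p_raw": float(row["p_raw"]),
                "p_fdr": float(row["p_fdr"]),
            }
            for name, row in fit.coef.iterrows()
        },
        "A1": fit.A1,
        "phi1_deg": fit.phi1_deg,
        "r2": fit.r2,
        "F": fit.F,
        "p_model": fit.p_model,
        "method": fit.method,
        "aligned": fit.aligned,
        "n_obs": fit.n_obs,
        "n_subjects": fit.n_subjects,
    }


def _seed_for(base_seed: int, label: str) -> int:
    """Stable per-stage substream seed (< 2**31)."""
    h = hashlib.sha256(f"{base_seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute the full analysis chain and return a `StudyReport`."""
    if config.preset is not None:
        params = synthgen.CohortParams(seed=_seed_for(config.seed, "cohort"))
        scores = synthgen.generate_cohort(params)
        provenance_input = {"preset": config.preset,
                            "ground_truth": synthgen.ground_truth(params)}
    else:
        scores = read_scores(config.scores_csv)
        provenance_input = {"scores_csv": str(config.scores_csv)}

    report = StudyReport(config_hash=config.config_hash(), seed=config.seed)
    report.provenance = {
        "input": provenance_input,
        "config": asdict(config),
        "design_flags": {
            "bootstrap_unit": config.bootstrap_unit,
            "best_phase_tie_break": "lowest phase",
            "jitter_halfwidth_deg": config.jitter_halfwidth_deg,
        },
    }
    logger.info("pipeline start: config=%s seed=%d", report.config_hash, config.seed)
    logger.info("design flags: %s", report.provenance["design_flags"])

    best_phases = {}
    for source in config.sources:
        try:
            centered = pm.center_scores(scores, source)
            aligned = pm.align_to_best_phase(scores, source)
        except Exception as exc:
            raise type(exc)(f"[stage centering/{source}] {exc}") from exc
        for method in config.methods:
            for is_aligned, data in ((False, centered), (True, aligned)):
                fit = pm.fit_harmonic(data, method=method, aligned=is_aligned)
                key = f"{source}/{method}/{'aligned' if is_aligned else 'absolute'}"
                report.fits[key] = _fit_record(fit)
        boot = pm.bootstrap_r2_compare(
            centered, n_boot=config.n_boot,
            seed=_seed_for(config.seed, f"boot:{source}"),
            unit=config.bootstrap_unit,
        )
        report.bootstrap[source] = {
            "n_boot": boot.n_boot,
            "n_skipped": boot.n_skipped,
            "mean_r2_ols": float(np.mean(boot.r2_ols)),
            "mean_r2_robust": float(np.mean(boot.r2_robust)),
            "t": boot.t,
            "p_robust_gt_ols": boot.p,
            "seed": boot.seed,
        }
        best = pm.best_phase_per_subject(scores, source)
        best_phases[source] = best
        summ = circ.circular_summary(best.to_numpy())
        z, rayleigh_p = circ.rayleigh_test(best.to_numpy())
        vm = circ.fit_von_mises(
            best.to_numpy(),
            jitter_halfwidth_deg=config.jitter_halfwidth_deg,
            seed=_seed_for(config.seed, f"jitter:{source}"),
        )
        report.circular[source] = {
            "best_phases_deg": [float(v) for v in best],
            "mean_deg": summ.mean_deg,
            "R": summ.R,
            "ang_dev_rad": summ.ang_dev_rad,
            "rayleigh_z": z,
            "rayleigh_p": rayleigh_p,
            "mu_deg": vm.mu_deg,
            "kappa": vm.kappa,
            "watson_u2": vm.watson_u2,
            "watson_p": vm.watson_p,
            "jittered": vm.jittered,
        }

    if {"target", "distractor"} <= set(config.sources):
        comp = pm.compare_amplitudes(
            pm.center_scores(scores, "target"),
            pm.center_scores(scores, "distractor"),
            method="robust" if "robust" in config.methods else "ols",
            n_boot=min(config.n_boot, 2000),
            seed=_seed_for(config.seed, "amp-compare"),
        )
        report.amplitude_comparison = {
            "a1_target": comp.a1_a, "a1_distractor": comp.a1_b,
            "diff": comp.diff, "se_diff": comp.se_diff,
            "t": comp.t, "df": comp.df, "p": comp.p,
        }
        homo_stat, homo_p = circ.concentration_homogeneity(
            best_phases["distractor"].to_numpy(),
            best_phases["target"].to_numpy(),
        )
        report.circular["concentration_homogeneity"] = {
            "stat": homo_stat, "p": homo_p,
            "order": "distractor vs target",
        }

    if "sham" in set(scores["source"]):
        anova = pm.compare_to_sham(scores)
        report.sham_anova = {
            "F": anova.F, "df_between": anova.df_between,
            "df_within": anova.df_within, "p": anova.p,
            "group_means": anova.group_means,
        }

    if config.out_dir is not None:
        write_report(report, config.out_dir, scores=scores,
                     make_figures=config.make_figures)
    logger.info("pipeline done: %d fits", len(report.fits))
    return report


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def fit_table(fit_record: dict) -> pd.DataFrame:
    """Regression table (rows A0/B1/B2[/A2]; estimate, CI, FDR p) with the
    F / p / r^2 footer carried in DataFrame attrs."""
    rows = []
    for name, c in fit_record["coefficients"].items():
        rows.append({
            "variable": name,
            "estimate_pct": c["estimate"],
            "ci_low_pct": c["ci_low"],
            "ci_high_pct": c["ci_high"],
            "p_fdr": c["p_fdr"],
        })
    table = pd.DataFrame(rows)
    table.attrs["footer"] = {
        "F": fit_record["F"], "p": fit_record["p_model"], "r2": fit_record["r2"],
    }
    return table


def write_report(report: StudyReport, out_dir: str | Path,
                 scores: pd.DataFrame | None = None,
                 make_figures: bool = False) -> None:
    """Write report.json, per-fit TSV tables and optional figures."""
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    body = {
        "config_hash": report.config_hash,
        "seed": report.seed,
        "fits": report.fits,
        "bootstrap": report.bootstrap,
        "circular": report.circular,
        "amplitude_comparison": report.amplitude_comparison,
        "sham_anova": report.sham_anova,
        "provenance": report.provenance,
    }
    (out / "report.json").write_text(json.dumps(body, indent=2, default=float))
    for key, rec in report.fits.items():
        table = fit_table(rec)
        name = key.replace("/", "_")
        footer = table.attrs["footer"]
        with open(out / "tables" / f"{name}.tsv", "w") as fh:
            table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
            fh.write(f"# F={footer['F']:.6g}\tp={footer['p']:.6g}\t"
                     f"r2={footer['r2']:.6g}\n")
    if make_figures and scores is not None:
        _write_figures(report, scores, out / "figures")


def _write_figures(report: StudyReport, scores: pd.DataFrame,
                   fig_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)
    phases = np.array(pm.STUDY_PHASES)
    grid = np.linspace(0, 360, 361)
    for source in ("target", "distractor"):
        key = f"{source}/robust/absolute"
        if key not in report.fits:
            key = f"{source}/ols/absolute"
            if key not in report.fits:
                continue
        rec = report.fits[key]
        centered = pm.center_scores(scores, source)
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
        for _, grp in centered.groupby("subject_id"):
            ax1.plot(grp["phase_deg"], grp["delta_cs"], "o", color="0.7",
                     ms=3, alpha=0.6)
        means = centered.groupby("phase_deg")["delta_cs"].mean()
        ax1.plot(means.index, means.values, "ko", ms=6)
        model = rec["A1"] * np.cos(np.radians(grid - rec["phi1_deg"]))
        ax1.plot(grid, model, "r-", lw=1.5)
        ax1.set_xticks(phases)
        ax1.set_xlabel("stimulation phase (deg)")
        ax1.set_ylabel("dCS (percentage points)")
        ax1.set_title(f"{source}: A1={rec['A1']:.2f}, phi1={rec['phi1_deg']:.0f} deg")
        cinfo = report.circular[source]
        angles = np.array(cinfo["best_phases_deg"])
        ax2.hist(angles, bins=np.arange(-45, 360, 90), color="0.8",
                 edgecolor="k")
        kappa = max(cinfo["kappa"], 1e-8)
        from scipy.stats import vonmises
        dens = vonmises.pdf(np.radians(grid), kappa,
                            loc=np.radians(cinfo["mu_deg"]))
        ax2.plot(grid, dens * 90 * len(angles), "r-", lw=1.5)
        ax2.set_xlabel("best phase (deg)")
        ax2.set_ylabel("subjects")
        ax2.set_title(f"R={cinfo['R']:.2f}, Rayleigh p={cinfo['rayleigh_p']:.2g}")
        fig.tight_layout()
        fig.savefig(fig_dir / f"{source}.png", dpi=110)
        plt.close(fig)
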