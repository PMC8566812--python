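"""Config-driven multi-exposure study orchestration.

A study is one outcome against any number of exposures.  Each exposure
runs through instrument selection, optional LD clumping, proxy
substitution, harmonization, the three estimators and the sensitivity
analyses; the primary (IVW) p-value is then held to the Bonferroni
threshold alpha / n_tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import ConfigurationError, EmptyHarmonizedSetError, MrToolsError
from .estimators import EggerEstimate, MrEstimate, ivw, labelled, mr_egger, weighted_median
from .harmonize import (
    HarmonizedSet,
    LdInfo,
    build_harmonized_set,
    clump,
    select_instruments,
)
from .sensitivity import (
    HeterogeneityResult,
    LeaveOneOutTable,
    cochran_q,
    flag_outliers,
    leave_one_out,
    single_snp_table,
)
from .summary_io import (
    TraitMeta,
    read_gwas_table,
    write_mr_report,
    write_mr_report_json,
)

logger = logging.getLogger("mrtools")

__all__ = ["TableSpec", "StudyConfig", "ExposureResult", "StudyReport", "run_study", "render_report"]


@dataclass
class TableSpec:
    """One summary-statistic table plus how to read it."""

    name: str
    path: str
    column_map: str | Mapping[str, str] | None = None
    trait_type: str = "continuous"
    effect_scale: str = "beta"
    n_samples: int | None = None
    delimiter: str | None = None

    def trait_meta(self) -> TraitMeta:
        return TraitMeta(self.name, self.trait_type, self.effect_scale, self.n_samples)

    def read(self):
        return read_gwas_table(
            self.path, self.column_map, self.trait_meta(), delimiter=self.delimiter
        )


@dataclass
class StudyConfig:
    """Declarative description of one multi-exposure MR study."""

    outcome: TableSpec
    exposures: list[TableSpec]
    p_instrument: float = 5e-8
    clump_r2: float = 0.01
    clump_window: int = 1_000_000
    proxy_r2: float = 0.8
    alpha: float = 0.05
    n_tests: int | None = None  # default: number of exposures
    palindromic_mode: str = "keep"
    n_boot: int = 1000
    seed: int | None = None
    ld_pairs_path: str | None = None
    proxy_table_path: str | None = None
    preselected: bool = False  # inputs already p-filtered and clumped

    def __post_init__(self):
        if not self.exposures:
            raise ConfigurationError("study needs at least one exposure")
        if not (0 < self.p_instrument < 1):
            raise ConfigurationError("p_instrument must be in (0,1)")
        if not (0 <= self.clump_r2 <= 1):
            raise ConfigurationError("clump_r2 must be in [0,1]")
        if self.clump_window <= 0:
            raise ConfigurationError("clump_window must be positive")
        if not (0 < self.proxy_r2 <= 1):
            raise ConfigurationError("proxy_r2 must be in (0,1]")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0,1)")

    @property
    def bonferroni_threshold(self) -> float:
        n = self.n_tests if self.n_tests is not None else len(self.exposures)
        return self.alpha / n

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "StudyConfig":
        """Load a study from a YAML file; keyword overrides win over the file."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "outcome" not in raw or "exposures" not in raw:
            raise ConfigurationError(f"{path}: config must define 'outcome' and 'exposures'")
        outcome = TableSpec(**raw.pop("outcome"))
        exposures = [TableSpec(**e) for e in raw.pop("exposures")]
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(outcome=outcome, exposures=exposures, **raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc


@dataclass
class ExposureResult:
    """Everything computed for one exposure → outcome analysis."""

    exposure: str
    outcome: str
    harmonized: HarmonizedSet | None = None
    estimates: list[MrEstimate] = field(default_factory=list)
    egger: EggerEstimate | None = None
    heterogeneity: HeterogeneityResult | None = None
    loo: LeaveOneOutTable | None = None
    single_snp: pd.DataFrame | None = None
    outliers: list[str] = field(default_factory=list)
    significant: bool | None = None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


@dataclass
class StudyReport:
    """Collected per-exposure results plus the study-wide thresholds."""

    results: list[ExposureResult]
    alpha: float
    n_tests: int

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests

    @property
    def any_failed(self) -> bool:
        return any(r.failed for r in self.results)


def _analyze_exposure(
    exposure_records, outcome_lookup, cfg: StudyConfig, name: str, ld: LdInfo | None,
    proxy_table,
) -> ExposureResult:
    res = ExposureResult(exposure=name, outcome=cfg.outcome.name)
    instruments = exposure_records
    if not cfg.preselected:
        instruments = select_instruments(instruments, cfg.p_instrument)
        if ld is not None:
            instruments = clump(instruments, ld, cfg.clump_r2, cfg.clump_window)
    if not instruments:
        res.error = "no instruments passed selection"
        return res
    try:
        h = build_harmonized_set(
            instruments,
            outcome_lookup,
            exposure_name=name,
            outcome_name=cfg.outcome.name,
            proxy_table=proxy_table,
            proxy_r2_min=cfg.proxy_r2,
            palindromic_mode=cfg.palindromic_mode,
        )
    except EmptyHarmonizedSetError as exc:
        res.error = f"empty harmonized set: {exc}"
        return res

    res.harmonized = h
    primary = labelled(ivw(h), name, cfg.outcome.name)
    res.estimates.append(primary)
    if h.n_snp >= 3:
        res.estimates.append(
            labelled(weighted_median(h, n_boot=cfg.n_boot, seed=cfg.seed), name, cfg.outcome.name)
        )
        res.egger = mr_egger(h)
        res.estimates.append(labelled(res.egger.slope, name, cfg.outcome.name))
    if h.n_snp >= 2:
        res.heterogeneity = cochran_q(h)
        res.loo = leave_one_out(h)
    res.single_snp = single_snp_table(h, n_boot=cfg.n_boot, seed=cfg.seed)
    res.outliers = flag_outliers(h)
    res.significant = bool(primary.pvalue < cfg.bonferroni_threshold)
    return res


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute the full study: every exposure against the one outcome.

    A failing exposure (empty harmonized set, no instruments) is recorded
    and the study continues; malformed configuration raises before any
    computation.
    """
    outcome_records = cfg.outcome.read()
    outcome_lookup = {r.snp_id: r for r in outcome_records}
    ld = LdInfo.from_pair_table(cfg.ld_pairs_path) if cfg.ld_pairs_path else None
    proxy_table = _read_proxy_table(cfg.proxy_table_path) if cfg.proxy_table_path else None

    results = []
    for spec in cfg.exposures:
        logger.info("analyzing %s -> %s", spec.name, cfg.outcome.name)
        try:
            records = spec.read()
        except MrToolsError as exc:
            results.append(
                ExposureResult(exposure=spec.name, outcome=cfg.outcome.name, error=str(exc))
            )
            continue
        results.append(
            _analyze_exposure(records, outcome_lookup, cfg, spec.name, ld, proxy_table)
        )
    n_tests = cfg.n_tests if cfg.n_tests is not None else len(cfg.exposures)
    return StudyReport(results=results, alpha=cfg.alpha, n_tests=n_tests)


def _read_proxy_table(path: str | Path):
    df = pd.read_csv(path, sep="\t")
    for col in ("snp", "proxy", "r2"):
        if col not in df.columns:
            raise ConfigurationError(f"proxy table lacks column {col!r}")
    table: dict[str, list[tuple]] = {}
    has_phase = "phase" in df.columns
    for row in df.itertuples(index=False):
        entry = (str(row.snp), str(row.proxy), float(row.r2))
        phase = getattr(row, "phase", None) if has_phase else None
        table.setdefault(entry[0], []).append(
            (entry[1], entry[2]) if phase is None or pd.isna(phase) else (entry[1], entry[2], str(phase))
        )
    return table


def render_report(report: StudyReport, out_dir: str | Path, plots: bool = False) -> list[Path]:
    """Write the consolidated and per-exposure tables (stable file set).

    Produces ``mr_report.tsv`` / ``mr_report.json`` (all estimates, one
    row per exposure × method, failed analyses included as explicit
    rows), plus ``<exposure>_single_snp.tsv``, ``<exposure>_loo.tsv``
    and ``<exposure>_audit.tsv`` per exposure.  With ``plots=True``,
    scatter / forest / leave-one-out figures are derived from those same
    tables (requires matplotlib).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    estimates = [e for r in report.results for e in r.estimates]
    report_path = out_dir / "mr_report.tsv"
    if estimates:
        write_mr_report(estimates, report_path)
        write_mr_report_json(estimates, out_dir / "mr_report.json")
    else:
        report_path.write_text(
            "exposure\toutcome\tmethod\tn_snp\tbeta\tse\tOR\tci_low\tci_high\tpvalue\n"
        )
    written.append(report_path)

    # study-level summary with significance flags and failures
    rows = []
    for r in report.results:
        if r.failed:
            rows.append(
                {"exposure": r.exposure, "outcome": r.outcome, "n_snp": 0,
                 "ivw_pvalue": "", "significant": "", "status": f"failed: {r.error}"}
            )
            continue
        primary = r.estimates[0]
        rows.append(
            {"exposure": r.exposure, "outcome": r.outcome, "n_snp": primary.n_snp,
             "ivw_pvalue": format(primary.pvalue, ".17g"),
             "significant": str(bool(r.significant)).lower(), "status": "ok"}
        )
    summary_path = out_dir / "study_summary.tsv"
    pd.DataFrame(rows).to_csv(summary_path, sep="\t", index=False)
    written.append(summary_path)

    for r in report.results:
        if r.failed:
            continue
        base = r.exposure.replace("/", "_")
        if r.single_snp is not None:
            p = out_dir / f"{base}_single_snp.tsv"
            r.single_snp.to_csv(p, sep="\t", index=False, float_format="%.17g")
            written.append(p)
        if r.loo is not None:
            p = out_dir / f"{base}_loo.tsv"
            r.loo.to_frame().to_csv(p, sep="\t", index=False, float_format="%.17g")
            written.append(p)
        audit_rows = [
            {"snp": d.snp_id, "action": "dropped", "detail": d.reason}
            for d in (r.harmonized.audit if r.harmonized else [])
        ] + [
            {"snp": s, "action": "kept", "detail": f}
            for s, f in zip(r.harmonized.snp_ids, r.harmonized.flags)
        ]
        p = out_dir / f"{base}_audit.tsv"
        pd.DataFrame(audit_rows, columns=["snp", "action", "detail"]).to_csv(
            p, sep="\t", index=False
        )
        written.append(p)
        if plots:
            written.extend(_render_plots(r, out_dir, base))
    return written


def _render_plots(res: ExposureResult, out_dir: Path, base: str) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    h = res.harmonized
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(h.X, h.Y, xerr=h.se_X, yerr=h.se_Y, fmt="o", ms=4, lw=1, alpha=0.8)
    for est in res.estimates:
        style = {"ivw": "-", "weighted_median": "--", "mr_egger_slope": ":"}[est.method]
        xs = pd.Series([0, max(abs(h.X)) * 1.05])
        intercept = res.egger.intercept if est.method == "mr_egger_slope" and res.egger else 0.0
        ax.plot(xs, intercept + est.beta * xs, style, label=est.method)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"SNP effect on {res.exposure}")
    ax.set_ylabel(f"SNP effect on {res.outcome} (log-OR)")
    ax.legend(fontsize=8)
    p = out_dir / f"{base}_scatter.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    if res.single_snp is not None:
        df = res.single_snp
        fig, ax = plt.subplots(figsize=(5, 0.35 * len(df) + 1))
        ys = range(len(df))
        ax.errorbar(
            df["OR"], ys,
            xerr=[df["OR"] - df["ci_low"], df["ci_high"] - df["OR"]],
            fmt="s", ms=4, lw=1, color="k",
        )
        ax.axvline(1.0, color="grey", lw=0.5)
        ax.set_yticks(list(ys))
        ax.set_yticklabels([f"{s} [{m}]" for s, m in zip(df["snp"], df["method"])], fontsize=7)
        ax.set_xlabel("OR")
        ax.set_xscale("log")
        p = out_dir / f"{base}_forest.png"
        fig.tight_layout()
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    if res.loo is not None:
        df = res.loo.to_frame()
        fig, ax = plt.subplots(figsize=(5, 0.35 * len(df) + 1))
        ys = range(len(df))
        ax.errorbar(
            df["beta"], ys,
            xerr=1.959964 * df["se"], fmt="o", ms=4, lw=1, color="k",
        )
        ax.axvline(0.0, color="grey", lw=0.5)
        ax.set_yticks(list(ys))
        ax.set_yticklabels(df["omitted_snp"], fontsize=7)
        ax.set_xlabel("IVW log-OR with SNP omitted")
        p = out_dir / f"{base}_loo.png"
        fig.tight_layout()
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
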