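"""Multi-exposure MR screening: selection → harmonization → estimation →
diagnostics → power → multiple-testing, with optional replication.

The screen runs every exposure against one outcome GWAS and emits:

* ``forest`` — one row per exposure × applicable method (beta, SE, OR and
  CI, p, instrument count), with Q / Egger-intercept diagnostics, power
  columns and Bonferroni significance flags;
* ``exclusions`` — exposures that could not be estimated (no genome-wide-
  significant variants, no valid instruments after harmonization), plus
  every per-variant harmonization exclusion. Nothing is silently dropped:
  each input exposure appears in exactly one of the two tables.

Bonferroni correction uses m = the number of exposures actually estimated,
within each correction family (exposures may be grouped into families via
their metadata; by default all belong to one family).
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, EmptyDatasetError
from .estimators import estimate_all
from .harmonize import harmonize_set
from .instruments import select_instruments
from .power import PowerInput, bonferroni_threshold, mr_power_binary
from .summary_io import LDPanel, SummaryDataset, read_ld_panel, read_summary

__all__ = ["ScreenConfig", "ScreenResult", "screen_datasets", "run_screen",
           "run_replication"]

FOREST_COLUMNS = [
    "exposure", "outcome", "family", "method", "n_snp", "beta", "se",
    "or", "or_low", "or_high", "pval", "q", "q_df", "q_pval",
    "egger_intercept", "egger_intercept_se", "egger_intercept_pval",
    "mean_f", "total_r2", "n_proxied",
    "power_or_0.9", "power_or_1.1", "bonferroni_m", "bonferroni_threshold",
    "bonferroni_significant",
]


@dataclass
class ScreenConfig:
    """File-level configuration of a screen run (loadable from YAML)."""

    outcome: str
    exposures: list[dict]  # each: {path, name?, family?, trait_type?, n_cases?, n_controls?}
    ld_panel: str | None = None
    replication_outcome: str | None = None
    outcome_meta: dict = field(default_factory=dict)
    replication_meta: dict = field(default_factory=dict)
    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    clump_window_kb: float = 10_000
    proxy_r2: float = 0.8
    use_proxies: bool = True
    palindromic_maf_limit: float = 0.3
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    outdir: str = "mrscreen_out"

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if not 0 <= self.clump_r2 <= 1:
            raise ConfigurationError("clump_r2 must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        for exp in self.exposures:
            if exp["path"] == self.outcome:
                print(
                    f"warning: exposure path {exp['path']} equals the outcome path; "
                    "two-sample independence is the caller's responsibility",
                    file=sys.stderr,
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ScreenResult:
    """Tables produced by one screen run."""

    forest: pd.DataFrame
    exclusions: pd.DataFrame
    scatter: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.forest.to_csv(outdir / "forest_table.tsv", sep="\t", index=False)
        self.exclusions.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
        self.scatter.to_csv(outdir / "scatter_data.tsv", sep="\t", index=False)
        diag_cols = ["exposure", "outcome", "n_snp", "q", "q_df", "q_pval",
                     "egger_intercept", "egger_intercept_se", "egger_intercept_pval"]
        primary = self.forest[self.forest["method"].isin(["ivw_mre", "ivw_fixed", "wald_ratio"])]
        primary[diag_cols].to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)


def _power_columns(total_r2: float, outcome: SummaryDataset, alpha: float) -> dict:
    """Power to detect OR 0.9 and 1.1 given the instruments' R² and outcome size."""
    n = outcome.n_total
    k = outcome.case_fraction
    out = {"power_or_0.9": np.nan, "power_or_1.1": np.nan}
    if n is None or k is None or not 0 < total_r2 < 1:
        return out
    for or_target in (0.9, 1.1):
        out[f"power_or_{or_target}"] = mr_power_binary(
            PowerInput(n=n, r2_xz=total_r2, k_case=k, or_target=or_target, alpha=alpha)
        )
    return out


def screen_datasets(
    exposures: list[SummaryDataset],
    outcome: SummaryDataset,
    panel: LDPanel,
    families: list[str] | None = None,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.01,
    clump_window_kb: float = 10_000,
    use_proxies: bool = False,
    proxy_r2: float = 0.8,
    palindromic_maf_limit: float = 0.3,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> ScreenResult:
    """Run the full screen over in-memory datasets.

    Exposures with zero usable instruments are excluded from estimation but
    listed with a reason. Bonferroni flags use m = exposures estimated in
    each family.
    """
    families = families or ["all"] * len(exposures)
    forest_rows: list[dict] = []
    excl_rows: list[dict] = []
    scatter_rows: list[dict] = []
    counters = {"exposures_in": len(exposures), "exposures_estimated": 0,
                "variants_selected": 0, "variants_harmonized": 0, "proxies_used": 0}

    for exp_i, (exposure, family) in enumerate(zip(exposures, families)):
        name = exposure.trait_name
        iv = select_instruments(exposure, panel, p_threshold, clump_r2, clump_window_kb)
        if len(iv) == 0:
            excl_rows.append(dict(exposure=name, variant_id="", scope="exposure",
                                  reason="no_genomewide_significant_variants"))
            continue
        counters["variants_selected"] += len(iv)
        hs = harmonize_set(iv, outcome, panel, use_proxies=use_proxies,
                           proxy_r2=proxy_r2,
                           palindromic_maf_limit=palindromic_maf_limit)
        for vid, reason in sorted(hs.exclusions.items()):
            excl_rows.append(dict(exposure=name, variant_id=vid, scope="variant",
                                  reason=reason))
        if hs.n_snp == 0:
            excl_rows.append(dict(exposure=name, variant_id="", scope="exposure",
                                  reason="no_valid_instruments_after_harmonization"))
            continue
        counters["variants_harmonized"] += hs.n_snp
        n_proxied = sum(h.proxy_used for h in hs.instruments)
        counters["proxies_used"] += n_proxied

        estimates, diag = estimate_all(hs, seed=seed + exp_i, n_boot=n_boot)
        counters["exposures_estimated"] += 1
        power = _power_columns(iv.total_r2, outcome, alpha)
        for est in estimates:
            forest_rows.append({
                "exposure": name, "outcome": outcome.trait_name, "family": family,
                "method": est.method, "n_snp": est.n_snp, "beta": est.beta,
                "se": est.se, "or": est.or_value, "or_low": est.or_low,
                "or_high": est.or_high, "pval": est.pval,
                "q": diag.q if diag else np.nan,
                "q_df": diag.q_df if diag else np.nan,
                "q_pval": diag.q_pval if diag else np.nan,
                "egger_intercept": diag.egger_intercept if diag else None,
                "egger_intercept_se": diag.egger_intercept_se if diag else None,
                "egger_intercept_pval": diag.egger_intercept_pval if diag else None,
                "mean_f": iv.mean_f, "total_r2": iv.total_r2,
                "n_proxied": n_proxied, **power,
            })
        for h in hs.instruments:
            scatter_rows.append(dict(exposure=name, variant_id=h.variant_id,
                                     beta_x=h.beta_x, se_x=h.se_x,
                                     beta_y=h.beta_y, se_y=h.se_y))

    if not forest_rows:
        raise EmptyDatasetError("no exposure could be estimated")

    forest = pd.DataFrame(forest_rows)
    # Bonferroni within correction family, m = exposures actually estimated
    primary_methods = {"ivw_mre", "ivw_fixed", "wald_ratio"}
    forest["bonferroni_m"] = 0
    forest["bonferroni_threshold"] = np.nan
    forest["bonferroni_significant"] = False
    for family, sub in forest.groupby("family"):
        m = sub["exposure"].nunique()
        thr = bonferroni_threshold(alpha, m)
        mask = forest["family"] == family
        forest.loc[mask, "bonferroni_m"] = m
        forest.loc[mask, "bonferroni_threshold"] = thr
        forest.loc[mask, "bonferroni_significant"] = (
            forest.loc[mask, "method"].isin(primary_methods)
            & (forest.loc[mask, "pval"] < thr)
        )
    forest = forest.reindex(columns=FOREST_COLUMNS)

    exclusions = pd.DataFrame(excl_rows,
                              columns=["exposure", "variant_id", "scope", "reason"])
    scatter = pd.DataFrame(scatter_rows,
                           columns=["exposure", "variant_id", "beta_x", "se_x",
                                    "beta_y", "se_y"])
    manifest = dict(counters=counters, alpha=alpha, seed=seed,
                    p_threshold=p_threshold, clump_r2=clump_r2,
                    clump_window_kb=clump_window_kb, use_proxies=use_proxies,
                    outcome=outcome.trait_name)
    return ScreenResult(forest=forest, exclusions=exclusions, scatter=scatter,
                        manifest=manifest)


def _load_exposure(spec: dict) -> tuple[SummaryDataset, str]:
    ds = read_summary(
        spec["path"],
        column_map=spec.get("column_map"),
        trait_name=spec.get("name"),
        trait_type=spec.get("trait_type", "quantitative"),
        n_cases=spec.get("n_cases"),
        n_controls=spec.get("n_controls"),
    )
    return ds, spec.get("family", "all")


def _load_outcome(path: str, meta: dict) -> SummaryDataset:
    return read_summary(
        path,
        column_map=meta.get("column_map"),
        trait_name=meta.get("name", "outcome"),
        trait_type=meta.get("trait_type", "binary"),
        n_cases=meta.get("n_cases"),
        n_controls=meta.get("n_controls"),
    )


def run_screen(cfg: ScreenConfig) -> ScreenResult:
    """Run the screen from file paths per the configuration and write outputs."""
    outcome = _load_outcome(cfg.outcome, cfg.outcome_meta)
    loaded = [_load_exposure(s) for s in cfg.exposures]
    exposures = [d for d, _ in loaded]
    families = [f for _, f in loaded]
    if cfg.ld_panel is None:
        raise ConfigurationError("an LD panel path is required to run a screen")
    panel = read_ld_panel(cfg.ld_panel)

    result = screen_datasets(
        exposures, outcome, panel, families,
        p_threshold=cfg.p_threshold, clump_r2=cfg.clump_r2,
        clump_window_kb=cfg.clump_window_kb, use_proxies=cfg.use_proxies,
        proxy_r2=cfg.proxy_r2, palindromic_maf_limit=cfg.palindromic_maf_limit,
        alpha=cfg.alpha, n_boot=cfg.n_boot, seed=cfg.seed,
    )
    result.manifest["config_digest"] = cfg.digest()
    for stage, count in result.manifest["counters"].items():
        print(f"[mrscreen] {stage}: {count}", file=sys.stderr)
    result.write(cfg.outdir)
    return result


def run_replication(
    cfg: ScreenConfig,
    primary: ScreenResult,
    hits: list[str] | None = None,
) -> ScreenResult:
    """Re-run the screen against the replication outcome, restricted to hits.

    ``hits`` defaults to every estimated exposure. The returned forest table
    carries a ``sign_concordant`` column comparing each method's replication
    estimate with the primary estimate.
    """
    if cfg.replication_outcome is None:
        raise ConfigurationError("replication_outcome is not configured")
    outcome = _load_outcome(cfg.replication_outcome, cfg.replication_meta)
    if cfg.ld_panel is None:
        raise ConfigurationError("an LD panel path is required to run a screen")
    panel = read_ld_panel(cfg.ld_panel)

    loaded = [_load_exposure(s) for s in cfg.exposures]
    if hits:
        loaded = [(d, f) for d, f in loaded if d.trait_name in set(hits)]
        if not loaded:
            raise ConfigurationError("none of the requested hits match an exposure")
    exposures = [d for d, _ in loaded]
    families = [f for _, f in loaded]

    result = screen_datasets(
        exposures, outcome, panel, families,
        p_threshold=cfg.p_threshold, clump_r2=cfg.clump_r2,
        clump_window_kb=cfg.clump_window_kb, use_proxies=cfg.use_proxies,
        proxy_r2=cfg.proxy_r2, palindromic_maf_limit=cfg.palindromic_maf_limit,
        alpha=cfg.alpha, n_boot=cfg.n_boot, seed=cfg.seed,
    )
    primary_beta = primary.forest.set_index(["exposure", "method"])["beta"]
    concord = []
    for _, row in result.forest.iterrows():
        key = (row["exposure"], row["method"])
        if key in primary_beta.index:
            concord.append(bool(np.sign(primary_beta.loc[key]) == np.sign(row["beta"])))
        else:
            concord.append(None)
    result.forest["sign_concordant"] = concord
    result.manifest["replication_of"] = primary.manifest.get("outcome")
    result.write(Path(cfg.outdir) / "replication")
    return result
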