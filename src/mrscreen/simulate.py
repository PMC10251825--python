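"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator works directly on the standardized summary-statistic scale —
no individual-level genotypes are simulated. For each instrument j with
minor-allele frequency :math:`p_j`:

* the true exposure effect :math:`\\gamma_j` is drawn half-normal — the
  effect allele is reported as the exposure-increasing allele, the
  orientation under which directional pleiotropy is defined — and rescaled
  so the instruments jointly explain a target variance,
  :math:`\\sum_j 2 p_j (1-p_j) \\gamma_j^2 = R^2_{total}`;
* the exposure sampling SE is :math:`(2 n_x p_j (1-p_j))^{-1/2}` and the
  observed :math:`\\hat\\gamma_j` is drawn around the truth;
* the true outcome effect follows the instrumental-variable decomposition
  :math:`\\Gamma_j = \\beta \\gamma_j + \\alpha_j`, where :math:`\\beta` is
  the causal effect and :math:`\\alpha_j` a pleiotropic effect applied to a
  configurable fraction of instruments (none / balanced zero-mean /
  directional / correlated with :math:`\\gamma_j`, i.e. InSIDE-violating);
* the binary-outcome SE is :math:`(2 n_y p_j (1-p_j) K(1-K))^{-1/2}` for
  case fraction K, and :math:`\\hat\\Gamma_j` is drawn around the truth.

Realism knobs: LD decoy variants correlated with instruments (with exact
pairwise r² recorded in the panel, so clumping is deterministic), a
configurable fraction of palindromic A/T / C/G allele pairs, allele-
frequency jitter between samples (±0.02), and random allele-frame and
strand flips in the outcome file so harmonization is actually exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .harmonize import HarmonizedInstrumentSet, harmonize_set
from .instruments import InstrumentSet, select_instruments
from .summary_io import (
    CANONICAL_COLUMNS,
    LDPanel,
    SummaryDataset,
    write_ld_table,
    write_summary,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "ScreenFixture",
    "simulate_two_sample",
    "make_screen_fixture",
    "harmonized_truth_set",
    "instrument_set_from_truth",
    "write_screen_fixture",
]

_NON_PALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                          ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one synthetic two-sample dataset.

    Defaults are the package's reference study conditions: 100 instruments
    explaining 5% of a standardized exposure measured in 50,000 people
    (mean per-instrument F ≈ 25, above the F > 10 bar), against a rare
    binary outcome of 100,000 with case fraction 0.00217 — the case
    fraction of a registry liver-cancer GWAS (518 cases in 239,196).
    ``true_beta`` defaults to the global null.
    """

    n_snp: int = 100
    n_exposure: int = 50_000
    n_outcome: int = 100_000
    true_beta: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    total_r2: float = 0.05
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violating
    pleiotropy_sd: float = 0.01
    pleiotropy_mean: float = 0.02
    invalid_fraction: float = 0.3
    outcome_case_fraction: float = 0.00217
    n_ld_decoys: int = 0
    palindromic_fraction: float = 0.2
    eaf_jitter: float = 0.02
    frame_flip_fraction: float = 0.3
    strand_flip_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_snp < 1:
            raise ConfigurationError("n_snp must be >= 1")
        if not 0 < self.total_r2 < 1:
            raise ConfigurationError("total_r2 must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ConfigurationError("maf_range must be within (0, 0.5]")
        if not 0 <= self.invalid_fraction <= 1:
            raise ConfigurationError("invalid_fraction must be in [0, 1]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ConfigurationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not 0 < self.outcome_case_fraction < 1:
            raise ConfigurationError("outcome_case_fraction must be in (0, 1)")
        # per-SNP variance explained cannot exceed what the rarest allele allows
        per_snp = self.total_r2 / self.n_snp
        if per_snp >= 2 * lo * (1 - lo):
            raise ConfigurationError(
                f"total_r2={self.total_r2} infeasible for n_snp={self.n_snp} "
                f"with maf_range={self.maf_range}"
            )


@dataclass
class SimulationTruth:
    """Generating parameters a recovery test checks estimates against."""

    true_beta: float
    variant_ids: list[str]
    gamma: np.ndarray  # true per-variant exposure effects
    alpha: np.ndarray  # true per-variant pleiotropic effects on the outcome
    valid: np.ndarray  # False where alpha was applied
    realized_total_r2: float
    config: SimulationConfig


@dataclass
class ScreenFixture:
    """A multi-exposure screen: several exposures against one shared outcome."""

    exposures: list[SummaryDataset]
    outcome: SummaryDataset
    panel: LDPanel
    truths: list[SimulationTruth]


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.maximum(p, 5e-324)


def _draw_alpha(rng: np.random.Generator, cfg: SimulationConfig,
                gamma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pleiotropic effects and validity flags per the configured mode."""
    n = cfg.n_snp
    alpha = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    if cfg.pleiotropy_mode == "none" or cfg.invalid_fraction == 0:
        return alpha, valid
    n_invalid = int(round(cfg.invalid_fraction * n))
    if n_invalid == 0:
        return alpha, valid
    idx = rng.choice(n, size=n_invalid, replace=False)
    valid[idx] = False
    if cfg.pleiotropy_mode == "balanced":
        alpha[idx] = rng.normal(0.0, cfg.pleiotropy_sd, n_invalid)
    elif cfg.pleiotropy_mode == "directional":
        alpha[idx] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, n_invalid)
    else:  # inside_violating: pleiotropy tracks instrument strength
        g = gamma[idx]
        g_sd = np.std(gamma) or 1.0
        rho = 0.7
        alpha[idx] = (
            rho * cfg.pleiotropy_sd * g / g_sd
            + np.sqrt(1 - rho**2) * rng.normal(0.0, cfg.pleiotropy_sd, n_invalid)
            + cfg.pleiotropy_mean
        )
    return alpha, valid


def _assign_alleles(rng: np.random.Generator, n: int,
                    palindromic_fraction: float) -> tuple[list[str], list[str]]:
    eas, oas = [], []
    for j in range(n):
        if rng.random() < palindromic_fraction:
            ea, oa = _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
        else:
            ea, oa = _NON_PALINDROMIC_PAIRS[rng.integers(len(_NON_PALINDROMIC_PAIRS))]
        eas.append(ea)
        oas.append(oa)
    return eas, oas


def simulate_two_sample(
    cfg: SimulationConfig,
    id_prefix: str = "rs",
) -> tuple[SummaryDataset, SummaryDataset, LDPanel, SimulationTruth]:
    """Generate one exposure GWAS, one outcome GWAS, an LD panel and truth.

    All randomness flows from ``cfg.seed``: the same config reproduces the
    datasets bit-identically.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snp

    maf = rng.uniform(*cfg.maf_range, n)
    var_g = 2.0 * maf * (1.0 - maf)
    # oriented to the exposure-increasing allele (half-normal draw)
    gamma = np.abs(rng.standard_normal(n))
    gamma *= np.sqrt(cfg.total_r2 / np.sum(var_g * gamma**2))
    realized_r2 = float(np.sum(var_g * gamma**2))

    se_x = 1.0 / np.sqrt(2.0 * cfg.n_exposure * maf * (1.0 - maf))
    gamma_hat = gamma + se_x * rng.standard_normal(n)

    alpha, valid = _draw_alpha(rng, cfg, gamma)
    big_gamma = cfg.true_beta * gamma + alpha
    k = cfg.outcome_case_fraction
    se_y = 1.0 / np.sqrt(2.0 * cfg.n_outcome * maf * (1.0 - maf) * k * (1.0 - k))
    big_gamma_hat = big_gamma + se_y * rng.standard_normal(n)

    ids = [f"{id_prefix}{j + 1000}" for j in range(n)]
    chrom = [str((j % 22) + 1) for j in range(n)]
    pos = [10_000_000 + 25_000_000 * (j // 22) for j in range(n)]
    eas, oas = _assign_alleles(rng, n, cfg.palindromic_fraction)

    jit = cfg.eaf_jitter
    eaf_x = np.clip(maf + rng.uniform(-jit, jit, n), 1e-3, 1 - 1e-3)
    eaf_y = np.clip(maf + rng.uniform(-jit, jit, n), 1e-3, 1 - 1e-3)

    rows_x, rows_y = [], []
    positions: dict[str, tuple[str, int]] = {}
    r2_table: dict[tuple[str, str], float] = {}

    def frame(vid, ch, p, ea, oa, eaf, beta, se, nn):
        return dict(variant_id=vid, chromosome=ch, position=p, effect_allele=ea,
                    other_allele=oa, eaf=eaf, beta=beta, se=se,
                    pval=float(_two_sided_p(np.array([beta / se]))[0]), n=nn)

    def outcome_frame(vid, ch, p, ea, oa, eaf, beta, se, nn):
        # random allele-frame swaps and strand flips exercise harmonization;
        # the recorded statistics stay internally consistent
        if rng.random() < cfg.frame_flip_fraction:
            ea, oa, beta, eaf = oa, ea, -beta, 1.0 - eaf
        if {ea, oa} not in ({"A", "T"}, {"C", "G"}) and rng.random() < cfg.strand_flip_fraction:
            ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        return frame(vid, ch, p, ea, oa, eaf, beta, se, nn)

    for j in range(n):
        rows_x.append(frame(ids[j], chrom[j], pos[j], eas[j], oas[j],
                            float(eaf_x[j]), float(gamma_hat[j]), float(se_x[j]),
                            cfg.n_exposure))
        rows_y.append(outcome_frame(ids[j], chrom[j], pos[j], eas[j], oas[j],
                                    float(eaf_y[j]), float(big_gamma_hat[j]),
                                    float(se_y[j]), cfg.n_outcome))
        positions[ids[j]] = (chrom[j], pos[j])

    # LD decoys: correlated neighbours of instruments, with exact r2 recorded
    decoy_parent: dict[str, str] = {}
    for d in range(cfg.n_ld_decoys):
        pj = d % n
        r2 = float(rng.uniform(0.55, 0.95))
        did = f"{id_prefix}{d + 1000}_d"
        dmaf = float(np.clip(maf[pj] + rng.uniform(-jit, jit), 1e-3, 0.5))
        d_gamma = np.sqrt(r2) * gamma[pj]
        d_se_x = 1.0 / np.sqrt(2.0 * cfg.n_exposure * dmaf * (1.0 - dmaf))
        d_gamma_hat = d_gamma + d_se_x * rng.standard_normal()
        d_big = cfg.true_beta * d_gamma + np.sqrt(r2) * alpha[pj]
        d_se_y = 1.0 / np.sqrt(2.0 * cfg.n_outcome * dmaf * (1.0 - dmaf) * k * (1.0 - k))
        d_big_hat = d_big + d_se_y * rng.standard_normal()
        dpos = int(pos[pj] + rng.integers(-500_000, 500_001))
        dea, doa = _NON_PALINDROMIC_PAIRS[rng.integers(len(_NON_PALINDROMIC_PAIRS))]
        rows_x.append(frame(did, chrom[pj], dpos, dea, doa, dmaf,
                            float(d_gamma_hat), float(d_se_x), cfg.n_exposure))
        rows_y.append(outcome_frame(did, chrom[pj], dpos, dea, doa, dmaf,
                                    float(d_big_hat), float(d_se_y), cfg.n_outcome))
        positions[did] = (chrom[pj], dpos)
        key = (did, ids[pj]) if did <= ids[pj] else (ids[pj], did)
        r2_table[key] = r2
        for other, oparent in decoy_parent.items():
            if oparent == ids[pj]:
                okey = (did, other) if did <= other else (other, did)
                r2_table[okey] = r2 * r2_table[(other, oparent) if other <= oparent else (oparent, other)]
        decoy_parent[did] = ids[pj]

    exposure = SummaryDataset(
        trait_name=f"exposure_{id_prefix.rstrip('_')}",
        variants=pd.DataFrame(rows_x, columns=CANONICAL_COLUMNS),
        trait_type="quantitative",
    )
    n_cases = int(round(cfg.n_outcome * k))
    outcome = SummaryDataset(
        trait_name="outcome",
        variants=pd.DataFrame(rows_y, columns=CANONICAL_COLUMNS),
        trait_type="binary",
        n_cases=n_cases,
        n_controls=cfg.n_outcome - n_cases,
    )
    panel = LDPanel(variant_ids=list(positions), r2_table=r2_table, positions=positions)
    truth = SimulationTruth(
        true_beta=cfg.true_beta,
        variant_ids=ids,
        gamma=gamma,
        alpha=alpha,
        valid=valid,
        realized_total_r2=realized_r2,
        config=cfg,
    )
    return exposure, outcome, panel, truth


def instrument_set_from_truth(exposure: SummaryDataset,
                              truth: SimulationTruth) -> InstrumentSet:
    """Instrument set consisting exactly of the simulated true instruments.

    Bypasses selection — used by calibration studies that condition on the
    generated instruments rather than on the selection pipeline.
    """
    df = exposure.variants
    keep = df[df["variant_id"].isin(truth.variant_ids)].reset_index(drop=True)
    r2 = pd.Series(
        (2.0 * keep["eaf"] * (1.0 - keep["eaf"]) * keep["beta"] ** 2).to_numpy(),
        index=keep["variant_id"],
    )
    return InstrumentSet(
        exposure_name=exposure.trait_name,
        variants=keep,
        per_snp_r2=r2,
        total_r2=float(r2.sum()),
        mean_f=float("nan"),
        overall_f=float("nan"),
    )


def harmonized_truth_set(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    truth: SimulationTruth,
    palindromic_maf_limit: float = 0.3,
) -> HarmonizedInstrumentSet:
    """Harmonize the simulated true instruments against the outcome."""
    iv = instrument_set_from_truth(exposure, truth)
    return harmonize_set(iv, outcome, palindromic_maf_limit=palindromic_maf_limit)


def make_screen_fixture(
    n_exposures: int,
    seed: int = 0,
    true_beta: float | list[float] = 0.0,
    base_config: SimulationConfig | None = None,
) -> ScreenFixture:
    """A multi-exposure screen fixture sharing one outcome GWAS.

    Exposure instrument counts vary (every ninth exposure has exactly one
    instrument, exercising the Wald-ratio path — roughly the single-IV share
    of a real proteome screen); the remainder draw 3–8 instruments.
    Defaults mirror a proteome-scale exposure GWAS (n = 35,559) against a
    rare binary outcome (518 cases / 238,678 controls).
    """
    if n_exposures < 1:
        raise ConfigurationError("n_exposures must be >= 1")
    rng = np.random.default_rng(seed)
    base = base_config or SimulationConfig(
        n_exposure=35_559,
        n_outcome=239_196,
        outcome_case_fraction=518 / 239_196,
        n_ld_decoys=2,
    )
    betas = (
        list(true_beta) if isinstance(true_beta, (list, tuple, np.ndarray))
        else [float(true_beta)] * n_exposures
    )
    if len(betas) != n_exposures:
        raise ConfigurationError("true_beta list length must equal n_exposures")

    exposures: list[SummaryDataset] = []
    truths: list[SimulationTruth] = []
    outcome_tables: list[pd.DataFrame] = []
    all_positions: dict[str, tuple[str, int]] = {}
    all_r2: dict[tuple[str, str], float] = {}
    first_outcome: SummaryDataset | None = None

    for e in range(n_exposures):
        n_snp = 1 if e % 9 == 0 else int(rng.integers(3, 9))
        cfg = replace(
            base,
            n_snp=n_snp,
            true_beta=betas[e],
            total_r2=float(rng.uniform(0.01, 0.05)) * n_snp / 8 + 0.005,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        exp, out, panel, truth = simulate_two_sample(cfg, id_prefix=f"e{e}_rs")
        exp.trait_name = f"exposure_{e:03d}"
        exposures.append(exp)
        truths.append(truth)
        outcome_tables.append(out.variants)
        all_positions.update(panel.positions or {})
        if panel.r2_table:
            all_r2.update(panel.r2_table)
        first_outcome = out

    assert first_outcome is not None
    outcome = SummaryDataset(
        trait_name="outcome",
        variants=pd.concat(outcome_tables, ignore_index=True),
        trait_type="binary",
        n_cases=first_outcome.n_cases,
        n_controls=first_outcome.n_controls,
    )
    panel = LDPanel(variant_ids=list(all_positions), r2_table=all_r2,
                    positions=all_positions)
    return ScreenFixture(exposures=exposures, outcome=outcome, panel=panel,
                         truths=truths)


def write_screen_fixture(fixture: ScreenFixture, outdir: str | Path) -> dict[str, str]:
    """Write a screen fixture as TSV files readable by the summary IO layer.

    Returns a manifest mapping logical names to file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for ds in fixture.exposures:
        p = outdir / f"{ds.trait_name}.tsv"
        write_summary(ds, p)
        manifest[ds.trait_name] = str(p)
    outcome_path = outdir / "outcome.tsv"
    write_summary(fixture.outcome, outcome_path)
    manifest["outcome"] = str(outcome_path)
    panel_path = outdir / "ld_panel.tsv"
    write_ld_table(fixture.panel, panel_path)
    manifest["ld_panel"] = str(panel_path)
    truth_rows = []
    for ds, truth in zip(fixture.exposures, fixture.truths):
        for vid, g, a, v in zip(truth.variant_ids, truth.gamma, truth.alpha, truth.valid):
            truth_rows.append(dict(exposure=ds.trait_name, variant_id=vid,
                                   true_beta=truth.true_beta, gamma=g, alpha=a,
                                   valid=bool(v)))
    truth_path = outdir / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    manifest["truth"] = str(truth_path)
    return manifest
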