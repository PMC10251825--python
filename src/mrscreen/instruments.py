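"""Instrument selection: genome-wide significance filtering, LD clumping,
proxy search, and instrument-strength statistics.

Selection follows the standard multistep recipe: keep variants associated
with the exposure below the genome-wide threshold (p < 5e-8), clump them to
approximate pairwise independence (greedy by p-value, removing neighbours
within a +/-10,000 kb window whose r2 with the index is at or above 0.01),
and summarise strength with the F-statistic

    F = (R2 / k) / ((1 - R2) / (n - k - 1))

where R2 is the exposure variance explained by the instruments, k the
number of instruments and n the exposure sample size. F > 10 is the
conventional bar for adequate instrument strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DomainError, MRScreenError
from .summary_io import LDPanel, SummaryDataset, VariantAssociation, ld_r2

__all__ = [
    "InstrumentSet",
    "threshold_filter",
    "clump",
    "find_proxy",
    "per_snp_r2",
    "f_statistic",
    "FStatistic",
    "select_instruments",
]


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with strength accounting.

    ``mean_f`` is the mean of per-SNP F values (each with k = 1);
    ``overall_f`` evaluates the F formula once with R2 = ``total_r2`` and
    k = set size. Both are reported because published "mean F" columns do
    not pin down the aggregation.
    """

    exposure_name: str
    variants: pd.DataFrame
    per_snp_r2: pd.Series
    total_r2: float
    mean_f: float
    overall_f: float
    log: dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def to_frame(self) -> pd.DataFrame:
        """One-row summary mirroring a per-exposure instrument table."""
        return pd.DataFrame(
            [
                {
                    "exposure": self.exposure_name,
                    "n_iv": len(self),
                    "mean_f": self.mean_f,
                    "overall_f": self.overall_f,
                    "total_r2": self.total_r2,
                }
            ]
        )


def threshold_filter(exposure: SummaryDataset, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Variants associated with the exposure at p strictly below the threshold.

    Original row order is preserved; an empty result is legal.
    """
    df = exposure.variants
    return df[df["pval"] < p_threshold].reset_index(drop=True)


def clump(
    candidates: pd.DataFrame,
    panel: LDPanel,
    r2_threshold: float = 0.01,
    window_kb: float = 10_000,
) -> tuple[pd.DataFrame, list[str]]:
    """Greedy LD clumping of candidate variants.

    Repeatedly takes the remaining variant with the smallest p-value as an
    index (ties broken by chromosome, position, then id) and removes every
    remaining variant on the same chromosome within ±``window_kb``·1000 bp
    whose r² with the index is ≥ ``r2_threshold``.

    Returns the retained index variants (selection order) and the ids of
    candidates not covered by the panel, which are dropped up-front.
    """
    if candidates.empty:
        return candidates.copy(), []
    if candidates["position"].isna().any():
        raise MRScreenError("clump: candidates must have positions")

    covered = candidates["variant_id"].map(lambda v: v in panel)
    uncovered = list(candidates.loc[~covered, "variant_id"])
    pool = candidates[covered].copy()

    pool = pool.sort_values(
        ["pval", "chromosome", "position", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)

    window_bp = window_kb * 1000.0
    kept_rows = []
    active = pool.to_dict("records")
    while active:
        index = active.pop(0)
        kept_rows.append(index)
        remaining = []
        for row in active:
            if (
                row["chromosome"] == index["chromosome"]
                and abs(row["position"] - index["position"]) <= window_bp
                and ld_r2(panel, index["variant_id"], row["variant_id"]) >= r2_threshold
            ):
                continue
            remaining.append(row)
        active = remaining
    kept = pd.DataFrame(kept_rows, columns=list(pool.columns))
    return kept.reset_index(drop=True), uncovered


def find_proxy(
    target_id: str,
    outcome: SummaryDataset,
    panel: LDPanel,
    r2_min: float = 0.8,
) -> str | None:
    """Best proxy for a variant absent from the outcome GWAS.

    Among panel variants present in the outcome with r²(target, proxy)
    strictly greater than ``r2_min``, returns the one with maximal r²; ties
    broken by smaller genomic distance to the target (when positions are
    known), then lexicographic id. Returns ``None`` when no candidate
    qualifies or the target is not in the panel.
    """
    if target_id not in panel:
        return None
    target_pos = panel.position(target_id)
    outcome_ids = set(outcome.variants["variant_id"])

    best: tuple[float, float, str] | None = None  # (-r2, distance, id)
    for cand in panel.variant_ids:
        if cand == target_id or cand not in outcome_ids:
            continue
        r2 = ld_r2(panel, target_id, cand)
        if r2 <= r2_min:
            continue
        cand_pos = panel.position(cand)
        if target_pos is not None and cand_pos is not None and cand_pos[0] == target_pos[0]:
            dist = abs(cand_pos[1] - target_pos[1])
        else:
            dist = np.inf
        key = (-r2, dist, cand)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


def per_snp_r2(v: VariantAssociation) -> float:
    """Exposure variance explained by one variant of a standardized trait.

    Under Hardy–Weinberg the genotype variance is 2·eaf·(1−eaf), so the
    explained variance is 2·eaf·(1−eaf)·beta².
    """
    if v.eaf is None:
        raise DomainError(f"{v.variant_id}: eaf required for per-SNP R²")
    return 2.0 * v.eaf * (1.0 - v.eaf) * v.beta**2


class FStatistic(NamedTuple):
    f: float
    strong: bool  # True iff F > 10


def f_statistic(r2: float, k: int, n: int) -> FStatistic:
    """Instrument-strength F-statistic (R²/k) / ((1−R²)/(n−k−1)).

    The ``strong`` flag is True iff F > 10, the conventional bar for low
    weak-instrument bias.
    """
    if not 0 <= r2 < 1:
        raise DomainError(f"r2 must be in [0, 1), got {r2}")
    if k < 1 or n <= k + 1:
        raise DomainError(f"need n > k + 1 >= 2, got n={n}, k={k}")
    f = (r2 / k) / ((1.0 - r2) / (n - k - 1))
    return FStatistic(f=f, strong=f > 10.0)


def select_instruments(
    exposure: SummaryDataset,
    panel: LDPanel,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.01,
    window_kb: float = 10_000,
    n_override: int | None = None,
) -> InstrumentSet:
    """Threshold-filter and clump an exposure GWAS into an InstrumentSet.

    Variance-explained accounting uses per-variant eaf; variants with
    missing eaf are excluded from the R² sum (logged) but remain
    instruments. ``n_override`` substitutes for per-variant sample sizes
    when the file carries none.
    """
    candidates = threshold_filter(exposure, p_threshold)
    kept, uncovered = clump(candidates, panel, clump_r2, window_kb)

    log: dict[str, object] = {
        "n_candidates": len(candidates),
        "n_clumped_away": len(candidates) - len(uncovered) - len(kept),
        "uncovered_by_panel": uncovered,
    }

    r2_vals = {}
    f_vals = []
    missing_eaf = []
    for _, row in kept.iterrows():
        n = n_override if n_override is not None else (
            int(row["n"]) if pd.notna(row["n"]) else None
        )
        if pd.isna(row["eaf"]) or n is None:
            missing_eaf.append(row["variant_id"])
            continue
        r2 = 2.0 * float(row["eaf"]) * (1.0 - float(row["eaf"])) * float(row["beta"]) ** 2
        r2 = min(r2, 1.0 - 1e-12)
        r2_vals[row["variant_id"]] = r2
        f_vals.append(f_statistic(r2, 1, n).f)
    log["excluded_from_r2_accounting"] = missing_eaf

    total_r2 = float(sum(r2_vals.values()))
    mean_f = float(np.mean(f_vals)) if f_vals else float("nan")
    k = len(kept)
    n_all = n_override
    if n_all is None and kept["n"].notna().any():
        n_all = int(kept["n"].max())
    if k and n_all is not None and n_all > k + 1 and total_r2 < 1:
        overall_f = f_statistic(total_r2, k, n_all).f
    else:
        overall_f = float("nan")

    return InstrumentSet(
        exposure_name=exposure.trait_name,
        variants=kept,
        per_snp_r2=pd.Series(r2_vals, dtype=float),
        total_r2=total_r2,
        mean_f=mean_f,
        overall_f=overall_f,
        log=log,
    )
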