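"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR requires each instrument's exposure and outcome effects to be
expressed for the same effect allele on the same strand. Resolution order
for a shared variant:

1. exact allele match — kept as-is;
2. swapped effect/other alleles — outcome beta negated, frequency mirrored;
3. reverse-complement (strand flip) of 1 or 2 — relabelled then resolved;
4. palindromic pairs (A/T, C/G), where strand cannot be resolved from
   alleles: orientation is inferred from allele-frequency concordance when
   both minor-allele frequencies are below ``palindromic_maf_limit``,
   otherwise the variant is excluded as ambiguous;
5. anything else is excluded as allele-incompatible.

Instruments absent from the outcome can be proxy-substituted from an LD
panel (r² > 0.8 by default); the proxy contributes the outcome statistics
while the original exposure statistics are retained, with the proxy's
effect allele mapped through the sign of the dosage correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import EmptyDatasetError, HarmonizationError
from .instruments import InstrumentSet, find_proxy
from .summary_io import LDPanel, SummaryDataset, VariantAssociation, ld_r

__all__ = [
    "HarmonizedInstrument",
    "HarmonizedInstrumentSet",
    "harmonize_pair",
    "harmonize_set",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: exclusion reasons a harmonized set may log
EXCLUSION_REASONS = (
    "absent_in_outcome",
    "incompatible_alleles",
    "palindromic_ambiguous",
    "missing_eaf_for_palindrome",
)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One instrument with exposure and outcome effects on a common
    effect-allele frame."""

    variant_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    action: str
    eaf_x: float | None = None
    eaf_y: float | None = None
    proxy_used: bool = False
    proxy_id: str | None = None

    def __post_init__(self) -> None:
        if not (self.se_x > 0 and self.se_y > 0):
            raise ValueError(f"{self.variant_id}: standard errors must be > 0")


@dataclass
class HarmonizedInstrumentSet:
    """Aligned exposure/outcome effect pairs plus a per-variant exclusion log.

    Accounting invariant: every input instrument appears either in
    ``instruments`` or in ``exclusions``.
    """

    exposure_name: str
    outcome_name: str
    instruments: list[HarmonizedInstrument]
    exclusions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def n_snp(self) -> int:
        return len(self.instruments)

    def to_frame(self) -> pd.DataFrame:
        cols = ["variant_id", "beta_x", "se_x", "beta_y", "se_y", "eaf_x", "eaf_y",
                "action", "proxy_used"]
        rows = [
            {c: getattr(h, c) for c in cols}
            for h in self.instruments
        ]
        return pd.DataFrame(rows, columns=cols)

    def exclusions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.exclusions.items()), columns=["variant_id", "reason"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, exposure_name: str = "exposure",
                   outcome_name: str = "outcome") -> "HarmonizedInstrumentSet":
        """Build a set from a table with beta_x/se_x/beta_y/se_y columns."""
        instruments = [
            HarmonizedInstrument(
                variant_id=str(r.get("variant_id", i)),
                beta_x=float(r["beta_x"]), se_x=float(r["se_x"]),
                beta_y=float(r["beta_y"]), se_y=float(r["se_y"]),
                action=str(r.get("action", "kept")),
            )
            for i, r in df.iterrows()
        ]
        return cls(exposure_name, outcome_name, instruments)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _flip(a: str) -> str:
    return _COMPLEMENT[a]


def harmonize_pair(
    x: VariantAssociation,
    y: VariantAssociation,
    palindromic_maf_limit: float = 0.3,
) -> HarmonizedInstrument | str:
    """Harmonize one exposure/outcome record pair sharing a variant id.

    Returns a :class:`HarmonizedInstrument`, or an exclusion-reason string
    (one of :data:`EXCLUSION_REASONS`). ``palindromic_maf_limit`` = 0 always
    excludes palindromic variants; 0.5 always infers from frequency.
    """
    if x.variant_id != y.variant_id:
        raise HarmonizationError(f"variant id mismatch: {x.variant_id} vs {y.variant_id}")

    xe, xo = x.effect_allele, x.other_allele
    ye, yo = y.effect_allele, y.other_allele

    def build(beta_y: float, eaf_y: float | None, action: str) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            variant_id=x.variant_id,
            beta_x=x.beta, se_x=x.se, beta_y=beta_y, se_y=y.se,
            eaf_x=x.eaf, eaf_y=eaf_y, action=action,
        )

    if _is_palindromic(xe, xo):
        if {ye, yo} != {xe, xo}:
            return "incompatible_alleles"
        if x.eaf is not None and min(x.eaf, 1.0 - x.eaf) >= palindromic_maf_limit:
            return "palindromic_ambiguous"
        if x.eaf is None or y.eaf is None:
            return "missing_eaf_for_palindrome"
        if min(y.eaf, 1.0 - y.eaf) >= palindromic_maf_limit:
            return "palindromic_ambiguous"
        # strand is unresolvable from alleles; orient by frequency concordance
        eaf_y_as_is = y.eaf if ye == xe else 1.0 - y.eaf
        beta_y_as_is = y.beta if ye == xe else -y.beta
        if (x.eaf < 0.5) == (eaf_y_as_is < 0.5):
            return build(beta_y_as_is, eaf_y_as_is, "frequency_inferred")
        return build(-beta_y_as_is, 1.0 - eaf_y_as_is, "frequency_inferred")

    strand_flipped = False
    if {ye, yo} != {xe, xo}:
        ye2, yo2 = _flip(ye), _flip(yo)
        if {ye2, yo2} == {xe, xo}:
            ye, yo = ye2, yo2
            strand_flipped = True
        else:
            return "incompatible_alleles"

    if (ye, yo) == (xe, xo):
        action = "strand_flipped" if strand_flipped else "kept"
        return build(y.beta, y.eaf, action)
    # swapped effect/other: negate and mirror frequency
    action = "strand_flipped_and_sign_flipped" if strand_flipped else "sign_flipped"
    return build(-y.beta, None if y.eaf is None else 1.0 - y.eaf, action)


def _proxy_as_outcome_record(
    target: VariantAssociation,
    proxy: VariantAssociation,
    r_signed: float,
) -> VariantAssociation:
    """Re-express a proxy's outcome statistics on the target's alleles.

    A negative dosage correlation flips which target allele the proxy's
    effect allele tracks, so the beta is negated and the frequency mirrored.
    """
    if r_signed >= 0:
        beta, eaf = proxy.beta, proxy.eaf
    else:
        beta = -proxy.beta
        eaf = None if proxy.eaf is None else 1.0 - proxy.eaf
    return VariantAssociation(
        variant_id=target.variant_id,
        chromosome=proxy.chromosome,
        position=proxy.position,
        effect_allele=target.effect_allele,
        other_allele=target.other_allele,
        beta=beta, se=proxy.se, pval=proxy.pval, eaf=eaf, n=proxy.n,
    )


def harmonize_set(
    iv: InstrumentSet,
    outcome: SummaryDataset,
    panel: LDPanel | None = None,
    use_proxies: bool = False,
    proxy_r2: float = 0.8,
    palindromic_maf_limit: float = 0.3,
) -> HarmonizedInstrumentSet:
    """Harmonize every instrument of an exposure against an outcome GWAS.

    Instruments absent from the outcome are proxy-substituted when
    ``use_proxies`` and a panel are given, otherwise excluded as
    ``absent_in_outcome``. Every input instrument is accounted for either
    as a kept instrument or a logged exclusion.
    """
    if len(iv) == 0:
        raise EmptyDatasetError(f"{iv.exposure_name}: empty instrument set")

    outcome_ids = set(outcome.variants["variant_id"])
    kept: list[HarmonizedInstrument] = []
    exclusions: dict[str, str] = {}

    for _, row in iv.variants.iterrows():
        vid = str(row["variant_id"])
        x = _row_variant(row)
        proxy_id = None
        r_signed = 1.0
        if vid in outcome_ids:
            y = outcome.variant(vid)
        else:
            if use_proxies and panel is not None:
                proxy_id = find_proxy(vid, outcome, panel, r2_min=proxy_r2)
            if proxy_id is None:
                exclusions[vid] = "absent_in_outcome"
                continue
            proxy = outcome.variant(proxy_id)
            r_signed = ld_r(panel, vid, proxy_id)
            y = _proxy_as_outcome_record(x, proxy, r_signed)
        result = harmonize_pair(x, y, palindromic_maf_limit=palindromic_maf_limit)
        if isinstance(result, str):
            exclusions[vid] = result
            continue
        if proxy_id is not None:
            result = HarmonizedInstrument(
                variant_id=result.variant_id,
                beta_x=result.beta_x, se_x=result.se_x,
                beta_y=result.beta_y, se_y=result.se_y,
                eaf_x=result.eaf_x, eaf_y=result.eaf_y,
                action=result.action, proxy_used=True, proxy_id=proxy_id,
            )
        kept.append(result)

    return HarmonizedInstrumentSet(
        exposure_name=iv.exposure_name,
        outcome_name=outcome.trait_name,
        instruments=kept,
        exclusions=exclusions,
    )


def _row_variant(row: pd.Series) -> VariantAssociation:
    return VariantAssociation(
        variant_id=str(row["variant_id"]),
        chromosome=str(row["chromosome"]),
        position=int(row["position"]),
        effect_allele=str(row["effect_allele"]),
        other_allele=str(row["other_allele"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        pval=float(row["pval"]),
        eaf=None if pd.isna(row["eaf"]) else float(row["eaf"]),
        n=None if pd.isna(row["n"]) else int(row["n"]),
    )
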