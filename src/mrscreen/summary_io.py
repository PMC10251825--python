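"""Reading, validating and writing GWAS summary statistics and LD reference data.

The variant-level data model used throughout the package lives here:

* :class:`VariantAssociation` — one variant's association with one trait
  (effect allele, other allele, effect-allele frequency, beta, SE, p, n);
* :class:`SummaryDataset` — one GWAS (trait metadata plus a variant table);
* :class:`LDPanel` — an LD reference, either a sample × variant dosage
  matrix or a precomputed sparse pairwise r² table.

Summary statistics are tab-separated text with a header, one variant per
row (GWAS-SSF-like); gzip is accepted. Column names are mapped onto the
canonical schema via a user-supplied ``column_map`` with sensible defaults.
Coordinates are 1-based, matching GWAS summary-statistic convention.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyDatasetError,
    PanelLookupError,
    UndefinedLDError,
)

__all__ = [
    "VariantAssociation",
    "SummaryDataset",
    "LDPanel",
    "CANONICAL_COLUMNS",
    "DEFAULT_COLUMN_MAP",
    "read_summary",
    "write_summary",
    "read_ld_panel",
    "write_ld_table",
    "ld_r2",
    "ld_r",
]

#: canonical column order of the in-memory variant table
CANONICAL_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: default file-header names for each canonical column
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "snp",
    "chromosome": "chr",
    "position": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

_MANDATORY = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
]
_OPTIONAL = ["eaf", "n"]

_BASES = frozenset("ACGT")

#: smallest positive normal double — the floor applied to p-values of 0
PVAL_FLOOR = sys.float_info.min


@dataclass(frozen=True)
class VariantAssociation:
    """Summary association of one variant with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for a
    binary trait, SD units for a quantitative one); ``eaf`` is the
    effect-allele frequency and may be missing (``None``).
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: identical alleles")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if not 0 < self.pval <= 1:
            raise ValueError(f"{self.variant_id}: pval must be in (0, 1]")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ValueError(f"{self.variant_id}: eaf must be inside (0, 1)")

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class SummaryDataset:
    """One GWAS: trait metadata plus a variant table in canonical columns.

    ``variants`` is a :class:`pandas.DataFrame` with :data:`CANONICAL_COLUMNS`;
    ``qc`` counts rows dropped or repaired on ingest, keyed by reason.
    """

    trait_name: str
    variants: pd.DataFrame
    trait_type: str = "quantitative"
    n_cases: int | None = None
    n_controls: int | None = None
    qc: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ConfigurationError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary" and (self.n_cases is None or self.n_controls is None):
            raise ConfigurationError(
                f"{self.trait_name}: binary traits require n_cases and n_controls"
            )
        if self.variants["variant_id"].duplicated().any():
            dup = self.variants.loc[self.variants["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ConfigurationError(f"{self.trait_name}: duplicate variant_id {dup!r}")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def n_total(self) -> int | None:
        if self.n_cases is not None and self.n_controls is not None:
            return self.n_cases + self.n_controls
        n = self.variants["n"]
        return int(n.max()) if n.notna().any() else None

    @property
    def case_fraction(self) -> float | None:
        if self.n_cases is None or self.n_controls is None:
            return None
        return self.n_cases / (self.n_cases + self.n_controls)

    def variant(self, variant_id: str) -> VariantAssociation:
        """Return a single variant as a :class:`VariantAssociation`."""
        rows = self.variants[self.variants["variant_id"] == variant_id]
        if rows.empty:
            raise KeyError(variant_id)
        return _row_to_variant(rows.iloc[0])

    def has_variant(self, variant_id: str) -> bool:
        return variant_id in set(self.variants["variant_id"])


def _row_to_variant(row: pd.Series) -> VariantAssociation:
    eaf = row["eaf"]
    n = row["n"]
    return VariantAssociation(
        variant_id=str(row["variant_id"]),
        chromosome=str(row["chromosome"]),
        position=int(row["position"]),
        effect_allele=str(row["effect_allele"]),
        other_allele=str(row["other_allele"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        pval=float(row["pval"]),
        eaf=None if pd.isna(eaf) else float(eaf),
        n=None if pd.isna(n) else int(n),
    )


def _apply_qc(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Enforce variant-level invariants; drop offending rows, count reasons."""
    qc: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        k = int(mask.sum())
        if k:
            qc[reason] = qc.get(reason, 0) + k
            df = df[~mask]

    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    df["variant_id"] = df["variant_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = df[col].astype(float)

    drop(df["position"].isna() | df["beta"].isna() | df["se"].isna() | df["pval"].isna(),
         "missing_required_value")
    drop(~df["effect_allele"].isin(_BASES) | ~df["other_allele"].isin(_BASES),
         "non_snp_allele")
    drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    drop(df["se"] <= 0, "nonpositive_se")
    drop((df["pval"] < 0) | (df["pval"] > 1), "pval_out_of_range")

    floored = df["pval"] == 0
    if floored.any():
        qc["pval_floor"] = int(floored.sum())
        df.loc[floored, "pval"] = PVAL_FLOOR

    bad_eaf = df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1))
    if bad_eaf.any():
        qc["eaf_out_of_range_set_missing"] = int(bad_eaf.sum())
        df.loc[bad_eaf, "eaf"] = np.nan

    df["position"] = df["position"].astype(np.int64)
    return df.reset_index(drop=True), qc


def read_summary(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    trait_name: str | None = None,
    trait_type: str = "quantitative",
    n_cases: int | None = None,
    n_controls: int | None = None,
    sep: str = "\t",
) -> SummaryDataset:
    """Read a summary-statistics file into a validated :class:`SummaryDataset`.

    Rows violating the variant invariants are dropped and counted in the
    dataset's ``qc`` log; p-values recorded as 0 are floored to the smallest
    positive normal double (they only feed ranking and thresholding).

    Raises
    ------
    ConfigurationError
        if a mandatory mapped column is absent from the header.
    EmptyDatasetError
        if no valid rows remain.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep=sep)
    missing = [cmap[c] for c in _MANDATORY if cmap[c] not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory column(s) {missing}")

    df = pd.DataFrame({c: raw[cmap[c]] for c in _MANDATORY})
    for c in _OPTIONAL:
        df[c] = raw[cmap[c]] if cmap[c] in raw.columns else np.nan
    df = df[CANONICAL_COLUMNS]

    df, qc = _apply_qc(df)
    if df.empty:
        raise EmptyDatasetError(f"{path}: no valid variant rows after QC")
    return SummaryDataset(
        trait_name=trait_name or path.stem,
        variants=df,
        trait_type=trait_type,
        n_cases=n_cases,
        n_controls=n_controls,
        qc=qc,
    )


def write_summary(dataset: SummaryDataset, path: str | Path,
                  column_map: Mapping[str, str] | None = None) -> None:
    """Write a dataset as TSV using the default (or given) header names.

    Floats are written with full round-trip precision so that
    ``read_summary(write_summary(ds))`` reproduces every field bit-identically.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = dataset.variants.rename(columns=cmap)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LD reference panels


@dataclass
class LDPanel:
    """LD reference: dosages (samples × variants, entries in [0, 2]) or a
    sparse pairwise r² table keyed by unordered variant-id pairs.

    ``positions`` maps variant id → (chromosome, position) and is optional;
    it is used for proxy-search distance tie-breaking when available.
    """

    variant_ids: list[str]
    dosages: np.ndarray | None = None
    r2_table: dict[tuple[str, str], float] | None = None
    positions: dict[str, tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if self.dosages is None and self.r2_table is None:
            raise ConfigurationError("LDPanel needs dosages or an r2 table")
        if self.dosages is not None:
            self.dosages = np.asarray(self.dosages, dtype=float)
            if self.dosages.shape[1] != len(self.variant_ids):
                raise ConfigurationError("dosage matrix width != number of variant ids")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def position(self, variant_id: str) -> tuple[str, int] | None:
        if self.positions is None:
            return None
        return self.positions.get(variant_id)


def _table_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def ld_r(panel: LDPanel, id_a: str, id_b: str) -> float:
    """Signed LD correlation r between two panel variants.

    For dosage panels this is the Pearson correlation of the dosage vectors.
    Table panels store only r²; the sign is taken as positive (documented
    limitation — proxy alignment from a table panel assumes concordant
    dosage coding).
    """
    for v in (id_a, id_b):
        if v not in panel:
            raise PanelLookupError(v)
    if id_a == id_b:
        return 1.0
    if panel.dosages is not None:
        # canonical column order makes the result exactly symmetric in floats
        i, j = sorted((panel._index[id_a], panel._index[id_b]))
        x = panel.dosages[:, i]
        y = panel.dosages[:, j]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            bad = panel.variant_ids[i if sx == 0 else j]
            raise UndefinedLDError(f"zero-variance dosage vector for {bad}")
        return float(np.corrcoef(x, y)[0, 1])
    assert panel.r2_table is not None
    r2 = panel.r2_table.get(_table_key(id_a, id_b), 0.0)
    return float(np.sqrt(r2))


def ld_r2(panel: LDPanel, id_a: str, id_b: str) -> float:
    """Squared LD correlation between two panel variants; symmetric, in [0, 1]."""
    r = ld_r(panel, id_a, id_b)
    return min(r * r, 1.0)


def read_ld_panel(path: str | Path) -> LDPanel:
    """Read an LD panel from disk.

    Two formats are accepted: a three-column TSV ``id_a  id_b  r2`` (sparse
    pairwise table), or a whitespace-delimited dosage matrix with a
    variant-id header row and one sample per line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
    if [h.lower() for h in header[:3]] == ["id_a", "id_b", "r2"]:
        tab = pd.read_csv(path, sep="\t")
        table: dict[tuple[str, str], float] = {}
        ids: list[str] = []
        seen = set()
        for a, b, r2 in zip(tab["id_a"].astype(str), tab["id_b"].astype(str), tab["r2"]):
            r2 = float(r2)
            if not 0 <= r2 <= 1:
                raise ConfigurationError(f"{path}: r2 {r2} outside [0, 1] for ({a}, {b})")
            table[_table_key(a, b)] = r2
            for v in (a, b):
                if v not in seen:
                    seen.add(v)
                    ids.append(v)
        return LDPanel(variant_ids=ids, r2_table=table)
    mat = pd.read_csv(path, sep=r"\s+")
    return LDPanel(variant_ids=[str(c) for c in mat.columns], dosages=mat.to_numpy(dtype=float))


def write_ld_table(panel: LDPanel, path: str | Path,
                   pairs: Iterable[tuple[str, str]] | None = None) -> None:
    """Write a panel's pairwise r² entries as a three-column TSV.

    Self-pairs (id, id, 1.0) are written for every panel variant so that
    panel membership — which determines clumping coverage — survives a
    round trip even for variants with no recorded LD partners.
    """
    rows = []
    if panel.r2_table is not None and pairs is None:
        rows = [(v, v, 1.0) for v in panel.variant_ids]
        items = sorted(panel.r2_table.items())
        rows += [(a, b, r2) for (a, b), r2 in items if a != b]
    else:
        if pairs is None:
            raise ConfigurationError("dosage panels require an explicit pair list to export")
        for a, b in pairs:
            rows.append((a, b, ld_r2(panel, a, b)))
    pd.DataFrame(rows, columns=["id_a", "id_b", "r2"]).to_csv(path, sep="\t", index=False)
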