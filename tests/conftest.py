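import numpy as np
import pandas as pd
import pytest

from mrscreen import VariantAssociation


def random_effects_frame(rng: np.random.Generator, n_snp: int) -> pd.DataFrame:
    """Random harmonized effect table with positive SEs."""
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(n_snp)],
            "beta_x": rng.normal(0.05, 0.02, n_snp),
            "se_x": rng.uniform(0.002, 0.01, n_snp),
            "beta_y": rng.normal(0.01, 0.05, n_snp),
            "se_y": rng.uniform(0.01, 0.08, n_snp),
        }
    )


def make_variant(**kw) -> VariantAssociation:
    base = dict(
        variant_id="rs1",
        chromosome="1",
        position=1_000_000,
        effect_allele="A",
        other_allele="G",
        beta=0.1,
        se=0.01,
        pval=1e-10,
        eaf=0.3,
        n=50_000,
    )
    base.update(kw)
    return VariantAssociation(**base)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
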