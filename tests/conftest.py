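import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from apoepgs import GenotypeMatrix, SummaryStats  # noqa: E402


def make_stats(rows) -> SummaryStats:
    """Build SummaryStats from (vid, chrom, pos, eff, oth, beta, p) tuples."""
    return SummaryStats(
        pd.DataFrame(
            rows,
            columns=[
                "variant_id", "chromosome", "position",
                "effect_allele", "other_allele", "beta", "p_value",
            ],
        )
    )


def make_geno(individual_ids, variant_rows, dosages) -> GenotypeMatrix:
    """Build a GenotypeMatrix from (vid, chrom, pos, counted, alt) tuples."""
    variants = pd.DataFrame(
        variant_rows,
        columns=["variant_id", "chromosome", "position", "counted_allele", "alt_allele"],
    )
    return GenotypeMatrix(list(individual_ids), variants, np.asarray(dosages, float))


@pytest.fixture
def small_stats():
    return make_stats(
        [
            ("rs1", "1", 100, "A", "G", 0.30, 0.005),
            ("rs2", "2", 200, "C", "T", -0.20, 0.02),
            ("rs3", "19", 45_400_000, "A", "C", 0.50, 0.5),
        ]
    )


@pytest.fixture
def small_geno():
    return make_geno(
        ["s1", "s2"],
        [
            ("rs1", "1", 100, "A", "G"),
            ("rs2", "2", 200, "T", "C"),
            ("rs3", "19", 45_400_000, "A", "C"),
        ],
        [[0.0, 1.0, 2.0], [2.0, 2.0, 0.0]],
    )
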