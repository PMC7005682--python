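import numpy as np
import pandas as pd
import pytest

from ffapls.genetics import GenotypeTable


def make_table_from_counts(locus: str, counts: dict[str, int],
                           alleles: tuple[str, ...] | None = None) -> GenotypeTable:
    """Genotype table for one locus with exact genotype counts."""
    calls = []
    for gt, n in counts.items():
        calls.extend([gt] * n)
    df = pd.DataFrame({locus: calls}, index=[f"S{i:04d}" for i in range(len(calls))])
    return GenotypeTable(calls=df, alleles={locus: alleles} if alleles else {})


@pytest.fixture
def table_from_counts():
    return make_table_from_counts


@pytest.fixture
def two_locus_table():
    """Hand-built 2-locus table with phase ambiguity (double heterozygotes)."""
    rows = (
        [("A/A", "C/C")] * 5 + [("A/G", "C/T")] * 6 + [("G/G", "T/T")] * 3
        + [("A/G", "C/C")] * 3 + [("A/A", "C/T")] * 2 + [("G/G", "C/T")] * 1
    )
    df = pd.DataFrame(rows, columns=["L1", "L2"],
                      index=[f"S{i:02d}" for i in range(len(rows))])
    return GenotypeTable(calls=df, alleles={"L1": ("A", "G"), "L2": ("C", "T")})
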