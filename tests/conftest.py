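import numpy as np
import pytest

from ssda import CountMatrix


@pytest.fixture
def toy_cm() -> CountMatrix:
    """3 features x 4 samples with two balanced groups."""
    counts = np.array(
        [
            [10, 20, 30, 40],
            [5, 0, 2, 1],
            [100, 80, 120, 90],
        ]
    )
    return CountMatrix(
        ["geneA", "geneB", "geneC"],
        ["s1", "s2", "s3", "s4"],
        counts,
        conditions=np.array(["H", "H", "BV", "BV"], dtype=object),
    )


@pytest.fixture
def toy_counts_tsv(tmp_path):
    p = tmp_path / "counts.tsv"
    p.write_text(
        "feature\ts1\ts2\ts3\ts4\n"
        "geneA\t10\t20\t30\t40\n"
        "geneB\t5\t0\t2\t1\n"
        "geneC\t100\t80\t120\t90\n"
    )
    return p


@pytest.fixture
def toy_conditions_tsv(tmp_path):
    p = tmp_path / "cond.tsv"
    p.write_text("s1\tH\ns2\tH\ns3\tBV\ns4\tBV\n")
    return p


@pytest.fixture
def medium_cm():
    """A 60-feature x 12-sample backbone small enough for fast pipeline runs."""
    from ssda import nb_backbone

    cm, _ = nb_backbone(
        n_features=60, n_per_group=6, n_invariant=5, n_scale_features=5,
        lib_size_range=(5_000, 20_000), seed=11,
    )
    return cm
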