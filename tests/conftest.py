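import numpy as np
import pandas as pd
import pytest

from barseqcls import (
    CountMatrix,
    SampleMeta,
    TagRecord,
    build_database,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_tags():
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))

    def seq(n):
        return "".join(rng.choice(bases, size=n))

    return [
        TagRecord("SPAC1.01", "up", seq(20), seq(33)),
        TagRecord("SPAC1.01", "dn", seq(20), seq(33)),
        TagRecord("SPAC2.02", "up", seq(20), seq(33)),
        TagRecord("SPAC3.03", "dn", seq(20), seq(33)),
    ]


@pytest.fixture
def tiny_db(tiny_tags):
    return build_database(tiny_tags, indexes=("AACG", "CCTA"))


def make_count_matrix(cells, samples):
    """Build a CountMatrix from {(gene, tag): {sample_id: count}}."""
    index = pd.MultiIndex.from_tuples(sorted(cells), names=["gene_id", "tag_kind"])
    df = pd.DataFrame(0, index=index, columns=[m.sample_id for m in samples], dtype=int)
    for key, per_sample in cells.items():
        for sid, n in per_sample.items():
            df.loc[key, sid] = n
    return CountMatrix(counts=df, samples=samples)


def cls_samples(n_replicates=2, timepoints=(0.0, 4.0, 8.0, 12.0, 14.0)):
    metas = []
    for rep in range(1, n_replicates + 1):
        for t in timepoints:
            metas.append(
                SampleMeta(
                    sample_id=f"rep{rep}_t{t:g}",
                    replicate=rep,
                    timepoint=t,
                    unit="weeks",
                    role="reference" if t == timepoints[0] else "aged",
                )
            )
    return metas
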