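import numpy as np
import pytest

from strainscan import Genotype, VariantRecord


def make_record(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    genotypes=None,
    depths=None,
    annotations=None,
):
    """Small VariantRecord builder: genotypes given as 'A'/'R'/'M' strings."""
    code = {"A": Genotype.ALT, "R": Genotype.REF, "M": Genotype.MISSING}
    genotypes = genotypes or "A" * 4
    samples = [f"s{i + 1}" for i in range(len(genotypes))]
    gts = {s: code[c] for s, c in zip(samples, genotypes)}
    if depths is None:
        dps = {s: 20 for s in samples}
    else:
        dps = {s: d for s, d in zip(samples, depths)}
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes=gts,
        sample_depths=dps,
        site_annotations=dict(annotations or {}),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_genome():
    """A deterministic 2-chromosome genome, built without the generator."""
    rng = np.random.default_rng(99)
    bases = np.array(list("ACGT"))
    return {
        "chrA": "".join(rng.choice(bases, size=3000)),
        "chrB": "".join(rng.choice(bases, size=2000)),
    }
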