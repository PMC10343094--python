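import numpy as np
import pytest

from zwpar import synth, winstats


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A quick 1 Mb-PAR bundle shared by tests that only need valid files."""
    cfg = synth.SynthConfig(par_length=1_000_000, slr_length=400_000,
                            gen_window=100_000, marker_spacing=100_000,
                            seed=7)
    return synth.generate_dataset(cfg, tmp_path_factory.mktemp("small_bundle"))


@pytest.fixture(scope="session")
def small_variants(small_bundle):
    return winstats.VariantTable.from_vcf(small_bundle.vcf, small_bundle.sexes)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def toy_variant_table(pos, alt_counts, sexes, ploidy=None, depth=None,
                      chrom="chrZ", **annots):
    """Construct a VariantTable from plain arrays (test helper)."""
    import pandas as pd

    alt_counts = np.asarray(alt_counts, dtype=np.int8)
    n, m = alt_counts.shape
    if ploidy is None:
        ploidy = np.where(alt_counts == winstats.MISSING, 0, 2).astype(np.int8)
    if depth is None:
        depth = np.full((n, m), 30, dtype=np.int32)
    defaults = {"QUAL": 100.0, "QD": 20.0, "MQ": 55.0, "MQRankSum": 0.0,
                "FS": 1.0, "ReadPosRankSum": 0.0, "SOR": 1.0}
    defaults.update(annots)
    sites = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(pos, dtype=np.int64),
        "ref": "A", "alt": "T",
        **{k: np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
           for k, v in defaults.items()},
    })
    return winstats.VariantTable(
        sites=sites, samples=[f"s{i}" for i in range(m)],
        sexes=np.asarray(sexes), alt_counts=alt_counts,
        ploidy=np.asarray(ploidy, dtype=np.int8),
        depth=np.asarray(depth, dtype=np.int32))
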