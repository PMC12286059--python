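import numpy as np
import pytest

from nanoage import cohort, io
from nanoage.simulate import SimConfig, make_fixtures, simulate_cohort


@pytest.fixture(scope="session")
def fixtures(tmp_path_factory):
    """The bundled fixture set (bedMethyl, GFF3, chains, manifests, maps)."""
    return make_fixtures(tmp_path_factory.mktemp("fixtures"))


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small simulated cohort shared by read-only tests."""
    cfg = SimConfig(seed=5, n_null=60, n_pos=20, n_neg=20)
    return cfg, simulate_cohort(cfg, tmp_path_factory.mktemp("cohort"))


def load_complete_matrix(result, mod="m", min_cov=5):
    """Sample sheet -> aggregated, depth-filtered, complete-case matrix."""
    sheet = io.read_sample_sheet(result.sample_sheet)
    per = {s.sample_id: io.read_bedmethyl(p) for s, p in sheet}
    mat = cohort.aggregate(per, [s for s, _ in sheet], mod)
    return cohort.complete_cases(cohort.filter_coverage(mat, min_cov))


def random_records(rng, n, chroms=("chr1", "chr2"), max_cov=200):
    """Arbitrary valid MethylRecords (distinct sites) for round-trip tests."""
    out = []
    positions = rng.choice(10_000, size=n, replace=False)
    for pos in positions:
        cov = int(rng.integers(0, max_cov))
        nm = int(rng.integers(0, cov + 1))
        out.append(
            io.MethylRecord(
                site=io.CpGSite(
                    str(rng.choice(chroms)), int(pos), str(rng.choice(["+", "-", "."]))
                ),
                mod_code=str(rng.choice(["m", "h"])),
                valid_coverage=cov,
                n_mod=nm,
                beta=nm / cov if cov else float("nan"),
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
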