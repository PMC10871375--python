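import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/helpers.py

from fedcube.aggregate import merge
from fedcube.nlp import load_default_dictionary
from fedcube.pipeline import run_etl, run_study, surveillance_study_spec
from fedcube.synthetic_ehr import SyntheticConfig, generate_population, write_site_exports

SECRET = "test-codebook-secret"


@pytest.fixture(scope="session")
def dictionary():
    return load_default_dictionary()


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_patients=400, n_sites=2, seed=42)


@pytest.fixture(scope="session")
def small_population(small_config):
    return generate_population(small_config)


@pytest.fixture(scope="session")
def small_network(small_population, tmp_path_factory):
    """A written two-site export plus its ETL outputs and site matrices."""
    exports, truth = small_population
    root = tmp_path_factory.mktemp("small_net")
    write_site_exports(exports, root / "export")
    spec = surveillance_study_spec()
    tables_by_site, matrices = {}, []
    for ex in exports:
        tables, _ = run_etl(root / "export" / ex.source_site,
                            root / "etl" / ex.source_site, SECRET)
        tables_by_site[ex.source_site] = tables
        matrices.append(run_study(tables, spec, ex.source_site))
    return {
        "root": root,
        "exports": exports,
        "truth": truth,
        "spec": spec,
        "tables": tables_by_site,
        "site_matrices": matrices,
        "merged": merge(matrices),
    }


@pytest.fixture(scope="session")
def network10k(tmp_path_factory):
    """The full study-conditions network: 10,000 patients across five sites,
    30% disease prevalence, note sensitivity 0.9 vs ICD coding 0.5."""
    config = SyntheticConfig(n_patients=10_000, n_sites=5, seed=20210301)
    exports, truth = generate_population(config)
    root = tmp_path_factory.mktemp("net10k")
    write_site_exports(exports, root / "export")
    tables_by_site = {}
    for ex in exports:
        tables, _ = run_etl(root / "export" / ex.source_site,
                            root / "etl" / ex.source_site, SECRET)
        tables_by_site[ex.source_site] = tables
    return {"root": root, "config": config, "exports": exports, "truth": truth,
            "tables": tables_by_site}
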