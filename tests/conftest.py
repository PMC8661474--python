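import numpy as np
import pytest

from nrrnet import (
    CatalogEntry,
    FeatureCatalog,
    FeatureTable,
    SampleMetadata,
    parse_lipid_name,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_catalog():
    """Two mediators (one plasma, one gene) and three lipids."""
    return FeatureCatalog(
        [
            CatalogEntry("P-OPN", "mediator_plasma", "P-OPN"),
            CatalogEntry("CASP1", "mediator_gene", "CASP1"),
            CatalogEntry("TG(50:1)", "lipid", "TG (50:1)", parse_lipid_name("TG (50:1)")),
            CatalogEntry("PC(O-34:3)", "lipid", "PC (O-34:3)", parse_lipid_name("PC (O-34:3)")),
            CatalogEntry("LPC(22:5)", "lipid", "LPC (22:5)", parse_lipid_name("LPC (22:5)")),
        ]
    )


@pytest.fixture
def paired_metadata():
    """Three complete patient-control pairs."""
    rows = []
    for k in range(1, 4):
        rows.append(SampleMetadata(f"pt{k}", "patient", f"pair{k}", k == 1))
        rows.append(SampleMetadata(f"ct{k}", "control", f"pair{k}", False))
    return rows


@pytest.fixture
def small_table(rng, paired_metadata):
    ids = [m.sample_id for m in paired_metadata]
    values = rng.lognormal(mean=2.0, sigma=0.5, size=(len(ids), 4))
    return FeatureTable(ids, ["f1", "f2", "f3", "f4"], values)
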