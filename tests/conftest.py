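import pytest

from sirnascreen import (ScreenDataset, SimConfig, WellRecord,
                         generate_primary_screen)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(n_genes=160, seed=11)


@pytest.fixture(scope="session")
def primary_screen(default_config):
    """A two-plate synthetic primary screen with planted regulators."""
    return generate_primary_screen(default_config)


@pytest.fixture()
def tiny_dataset() -> ScreenDataset:
    """Hand-built 8-well single-pool fixture (4 sample wells + controls)."""
    records = [
        WellRecord("P1", "B02", "GENEA", 1001, "M-000001-01", "sample",
                   True, "LPS", 4400.0, 2000.0, 1),
        WellRecord("P1", "B03", "GENEA", 1001, "M-000001-01", "sample",
                   True, "LPS", 4000.0, 2000.0, 2),
        WellRecord("P1", "B04", "GENEA", 1001, "M-000001-01", "sample",
                   True, "LPS", 4200.0, 2100.0, 3),
        WellRecord("P1", "B05", "GENEA", 1001, "M-000001-01", "sample",
                   True, "LPS", 3900.0, 1950.0, 4),
        WellRecord("P1", "A10", "", None, "D-001210-05", "NTC",
                   True, "LPS", 5000.0, 2000.0, 1),
        WellRecord("P1", "B10", "", None, "D-001210-05", "NTC",
                   False, "none", 500.0, 2000.0, 1),
        WellRecord("P1", "J10", "", None, "siRenilla-custom", "siRenilla",
                   False, "none", 40.0, 100.0, 1),
        WellRecord("P1", "M10", "", None, "M-008088-01", "siTLR4",
                   True, "LPS", 600.0, 2000.0, 1),
    ]
    return ScreenDataset.from_records("primary", records)
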