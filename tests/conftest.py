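import numpy as np
import pandas as pd
import pytest

import contambench as cb


@pytest.fixture(scope="session")
def default_design():
    return cb.build_design(83, 8, seed=0)


@pytest.fixture
def small_design():
    return cb.build_design(12, 2, seed=5)


@pytest.fixture
def profile_factory():
    """Build a ReadCountProfile from (taxon, label, reads) rows."""

    def make(rows, library_id="lib1", kit="Tn5_V", input_pg=5.0,
             replicate=1, meta=None):
        frame = pd.DataFrame(rows, columns=["taxon", "label", "reads"])
        profile = cb.ReadCountProfile(
            library_id=library_id, kit=kit, input_pg=input_pg,
            replicate=replicate, counts=frame,
            total_depth=int(frame["reads"].sum()), meta=meta or {})
        profile.validate()
        return profile

    return make


@pytest.fixture
def pool_factory():
    """Build a small contaminant pool with controllable randomness."""

    def make(kit="Tn5_V", n_genera=5, median_pg=1.0, dispersion=0.0,
             genus_sigma=0.0, seed=0):
        from contambench.mock_community import ContaminantGenus

        rng = np.random.default_rng(seed)
        genera = [
            ContaminantGenus(genus=f"Genus{i}", shared=True,
                             log_mean=float(rng.normal(0, 1.0)),
                             log_sigma=genus_sigma)
            for i in range(n_genera)
        ]
        pool = cb.ContaminantPool(kit=kit, genera=genera,
                                  load_median_pg=median_pg,
                                  load_dispersion=dispersion)
        pool.validate()
        return pool

    return make


@pytest.fixture
def no_endo():
    """Endogenous model contributing zero mass."""
    return cb.EndogenousModel(mass_fraction_of_input=0.0)
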