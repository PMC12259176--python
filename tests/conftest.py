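"""Shared fixtures: small seeded synthetic sessions and pseudopopulations."""

import numpy as np
import pytest

from memdecode import screen as sc
from memdecode import syndata as sd
from memdecode.screen import Pseudopopulation


def make_session(region="itc", n_units=60, n_images=120, seed=11,
                 levels=(1, 2, 4, 8), base_count=24, **overrides):
    """A compact synthetic session with everything downstream needs."""
    cfg = sd.itc_like(**overrides) if region == "itc" else sd.hc_like(**overrides)
    images = sd.gen_images(n_images, seed=seed)
    spec = sd.NBackSpec(levels=levels, base_count=base_count)
    sequence = sd.gen_sequence(images, spec, seed=seed)
    units = sd.gen_units(cfg, n_units, images, seed=seed)
    session = sd.simulate_session(units, sequence, images, cfg, seed=seed)
    return {"config": cfg, "images": images, "sequence": sequence,
            "units": units, "session": session, "seed": seed}


@pytest.fixture(scope="session")
def itc_bundle():
    return make_session("itc")


@pytest.fixture(scope="session")
def hc_bundle():
    return make_session("hc", seed=12)


@pytest.fixture(scope="session")
def itc_pop(itc_bundle):
    return sc.assemble_pseudopopulation([itc_bundle["session"]], seed=7,
                                        drop_empty_strata=True)


@pytest.fixture(scope="session")
def hc_pop(hc_bundle):
    return sc.assemble_pseudopopulation([hc_bundle["session"]], seed=7,
                                        drop_empty_strata=True)


def single_bin_pop(counts, memorability, window=(0.0, 200.0)):
    """Pseudopopulation with one time bin from a (U, P, 2) count array."""
    counts = np.asarray(counts)
    memorability = np.asarray(memorability, dtype=float)
    return Pseudopopulation(
        unit_ids=[f"u{i}" for i in range(counts.shape[0])],
        counts=counts[..., None].astype(np.int64),
        bin_edges=np.asarray(window, dtype=float),
        memorability=memorability,
        mb_bin=np.clip((memorability * 10).astype(int), 0, 9),
        n_back=np.zeros(counts.shape[1], dtype=int),
    )
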