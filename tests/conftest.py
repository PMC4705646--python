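import numpy as np
import pytest

from rnatopo import builder, energetics, euler, sampler, secstruct, synthetic

HELICES = ("P2", "P3", "P4", "P6", "P7", "P8", "P9", "P9A")
CONTACTS = (("L2", "J8"), ("L2", "J5"), ("L9", "J8"), ("L9", "J5"))


@pytest.fixture(scope="session")
def fixture_library():
    return synthetic.fixtures()


@pytest.fixture(scope="session")
def azoarcus_structure(fixture_library):
    return fixture_library["azoarcus"].structure


@pytest.fixture(scope="session")
def azoarcus_topology(fixture_library):
    fx = fixture_library["azoarcus"]
    return secstruct.decompose_topology(fx.structure, regions=fx.regions)


@pytest.fixture(scope="session")
def hairpin_chain(fixture_library):
    return fixture_library["hairpin"].build(seed=0)


@pytest.fixture(scope="session")
def azoarcus_chain(fixture_library):
    return fixture_library["azoarcus"].build(seed=1)


def _azoarcus_observers(chain):
    rec = euler.OrientationRecorder(chain, list(HELICES))
    obs = {"rg": lambda c: sampler.radius_of_gyration(c),
           "orient": rec.observer()}
    for a, b in CONTACTS:
        cdef = energetics.region_contact(chain, a, b, min_pairs=2)
        obs[f"contact_{a}_{b}"] = energetics.make_contact_observer(chain, cdef)
    cdef = energetics.region_contact(chain, "J3/4", "P6", min_pairs=1)
    obs["contact_J34_P6"] = energetics.make_contact_observer(chain, cdef)
    # relaxed-threshold coaxial proxy (thresholds are configurable; the
    # strict defaults fire too rarely in short unrestrained runs)
    obs["stack_loose"] = energetics.make_stacking_observer(
        chain, beta_min=120.0, gap_max=14.0)
    return rec, obs


def _run(chain, restraints, obs, seed, steps=500_000):
    config = sampler.SamplerConfig(
        total_steps=steps, steps_per_exchange=500, record_interval=20,
        seed=seed, equilibration_fraction=0.1,
    )
    return sampler.remd_run(chain, restraints, config, observers=obs)


class PooledRuns:
    """Concatenated production series of independent REMD runs."""

    def __init__(self, runs, recorder):
        self.runs = runs
        self.recorder = recorder
        self.exchange_attempts = runs[0].exchange_attempts
        self.exchange_accepts = runs[0].exchange_accepts
        self.exchange_rates = runs[0].exchange_rates

    def production(self, name):
        return np.concatenate([r.production(name) for r in self.runs])


@pytest.fixture(scope="session")
def azoarcus_run(azoarcus_chain):
    """Shared unrestrained ensemble: two independent REMD runs pooled
    (the slow global-arrangement modes decorrelate between runs)."""
    rec, obs = _azoarcus_observers(azoarcus_chain)
    runs = [_run(azoarcus_chain, None, obs, seed=seed, steps=300_000)
            for seed in (2024, 9090)]
    return PooledRuns(runs, rec)


@pytest.fixture(scope="session")
def th_run(azoarcus_chain):
    """Triple-helix-restrained companion ensemble.

    Restrained production starts from a fold-in stage (boosted NOE
    constants assemble the motif; the study's restrained runs start from
    the native fold), then samples with the printed constants."""
    chain = azoarcus_chain
    rec, obs = _azoarcus_observers(chain)
    restraints = builder.make_restraints("TH", chain)
    noe_rows = list(restraints.noe)

    def noe_stats(coords):
        d = np.array([np.linalg.norm(coords[i] - coords[j])
                      for (i, j, *_rest) in noe_rows])
        inside = [(row[2] <= dd <= row[3]) for row, dd in zip(noe_rows, d)]
        return np.array([d.max(), float(np.mean(inside))])

    obs["noe_stats"] = noe_stats
    start = sampler.fold_in_restraints(chain, restraints, seed=76)
    config = sampler.SamplerConfig(
        total_steps=400_000, steps_per_exchange=500, record_interval=20,
        seed=77, equilibration_fraction=0.1,
    )
    traj = sampler.remd_run(chain, restraints, config, observers=obs,
                            start_coords=start)
    traj.recorder = rec
    traj.noe_r_max = max(row[3] for row in noe_rows)
    stats = traj.observables.pop("noe_stats")
    traj.observables["noe_max_dist"] = stats[:, 0]
    traj.observables["noe_inside_frac"] = stats[:, 1]
    return traj


@pytest.fixture(scope="session")
def tlr_run(fixture_library):
    """Tethered TL/TLR reference system with the receptor hairpin held."""
    fx = fixture_library["tl_tlr_reference"]
    chain = fx.build(seed=2)
    restraints = synthetic.tlr_reference_restraints(chain, fx)
    cdef = energetics.region_contact(chain, "TL", "TLR", min_pairs=2)
    obs = {"contact": energetics.make_contact_observer(chain, cdef),
           "rg": lambda c: sampler.radius_of_gyration(c)}
    traj = _run(chain, restraints, obs, seed=4, steps=300_000)
    traj.chain = chain
    return traj


def contact_dg(traj, name, condition=None, seed=0):
    mask = traj.production(name).astype(bool)
    cond = None if condition is None else traj.production(condition).astype(bool)
    return energetics.contact_probability_from_mask(mask, condition=cond,
                                                    seed=seed)
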