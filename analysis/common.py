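"""Shared state for the numbered analysis scripts.

Every script derives the same phantom and study cohort deterministically
from the study configuration, so the scripts can run independently and
in any order while describing one consistent dataset.
"""

from pathlib import Path

from bmrisk.geometry import fill_morphometrics
from bmrisk.phantom import SimulationConfig, build_phantom, simulate_cohort
from bmrisk.pipeline import default_study_config

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def study_setup(n_patients: int | None = None, with_morphometrics: bool = True):
    """Phantom, interface distance map and the study cohort (seed fixed)."""
    cfg = default_study_config()
    ph_cfg = cfg["phantom"]
    phantom = build_phantom(
        spacing_mm=ph_cfg["spacing_mm"], shape=tuple(ph_cfg["shape"]), seed=ph_cfg["seed"]
    )
    sim = dict(cfg["simulation"], seed=SEED)
    if n_patients is not None:
        sim["n_patients"] = n_patients
    cohort = simulate_cohort(phantom, SimulationConfig(**sim))
    dmap = phantom.interface_dmap()
    if with_morphometrics:
        fill_morphometrics(
            [l for _, l in cohort.iter_lesions()],
            phantom.grid,
            dmap=dmap,
            atlases=phantom.atlases,
            brain_mask=phantom.brain_mask,
        )
    RESULTS.mkdir(exist_ok=True)
    return phantom, dmap, cohort
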