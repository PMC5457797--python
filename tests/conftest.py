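import numpy as np
import pandas as pd
import pytest

from gsdi.reference import NormativeReference, build_reference
from gsdi.simulate import (INFERIOR, SUPERIOR, DiscMetrics, EyeRecord,
                           SimulationConfig, ThicknessMap, generate_cohort)


def full_square_region(shape):
    """Region grid with no outside cells: top half superior, bottom inferior
    (first half of the columns for a 1-row profile)."""
    shape = tuple(shape)
    region = np.full(shape, INFERIOR, dtype=np.int8)
    if shape[0] == 1:
        region[0, : shape[1] // 2] = SUPERIOR
    else:
        region[: shape[0] // 2, :] = SUPERIOR
    return region


def constant_map(value, shape=(10, 10), modality="GCC"):
    return ThicknessMap(np.full(shape, float(value)),
                        full_square_region(shape), modality)


@pytest.fixture
def exact_ref():
    """Analytically exact reference: constant 100 um mean, SD 1 um, and a
    tight (1e-6) pattern-deviation null, over a 10x10 grid (GCC) and a
    1x20 profile (NFL).  Closed-form GLV/FLV values hold exactly here."""
    shapes = {"GCC": (10, 10), "NFL": (1, 20)}
    regions = {"GCC": full_square_region(shapes["GCC"]),
               "NFL": full_square_region(shapes["NFL"])}
    mean_maps = {m: np.full(s, 100.0) for m, s in shapes.items()}
    sd_maps = {m: np.full(s, 1.0) for m, s in shapes.items()}
    scalar = pd.DataFrame(
        {"mean": [100.0, 100.0, 100.0, 0.5, 0.1,
                  100.0, 100.0, 100.0, 0.5, 0.1, 0.4, 0.35, 0.2],
         "sd": [5.0] * 3 + [0.5, 0.1] + [5.0] * 3 + [0.5, 0.1, 0.1, 0.1, 0.05]},
        index=["gcc_overall_um", "gcc_superior_um", "gcc_inferior_um",
               "gcc_glv_pct", "gcc_flv_pct",
               "nfl_overall_um", "nfl_superior_um", "nfl_inferior_um",
               "nfl_glv_pct", "nfl_flv_pct", "vcdr", "hcdr", "rim_volume"])
    return NormativeReference(
        mean_maps=mean_maps, sd_maps=sd_maps, regions=regions,
        scalar_stats=scalar, n_eyes=20,
        pattern_mean_maps={m: np.full(s, 100.0) for m, s in shapes.items()},
        pattern_sd_maps={m: np.full(s, 1e-6) for m, s in shapes.items()},
    )


def make_eye(gcc_values, nfl_values, group="R", subject="S1", eye="OD",
             vcdr=0.4, md=0.0, psd=1.4, stage=None, rim=0.2,
             gcc_region=None, nfl_region=None):
    gcc_region = (full_square_region(np.shape(gcc_values))
                  if gcc_region is None else gcc_region)
    nfl_region = (full_square_region(np.shape(nfl_values))
                  if nfl_region is None else nfl_region)
    return EyeRecord(
        subject_id=subject, eye=eye, group=group, md_db=md, psd_db=psd,
        gcc_map=ThicknessMap(np.asarray(gcc_values, float), gcc_region, "GCC"),
        nfl_map=ThicknessMap(np.asarray(nfl_values, float), nfl_region, "NFL"),
        disc=DiscMetrics(vcdr=vcdr, hcdr=max(vcdr - 0.05, 0.0),
                         rim_volume=rim),
        true_stage=stage, age=60.0, sex="F", ethnicity="other")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_reference_eyes=24, n_normal_eyes=30,
                            n_glaucoma_eyes=50, grid_shape=(16, 16),
                            nfl_profile_len=32, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_reference(small_cohort):
    return build_reference([e for e in small_cohort if e.group == "R"])


@pytest.fixture(scope="session")
def default_study():
    """The default seeded study: full-size cohort, reference, feature table.

    Session-scoped because the headline cross-validation checks reuse it.
    """
    from gsdi.index import build_feature_table

    config = SimulationConfig(seed=2015)
    cohort = generate_cohort(config)
    ref = build_reference([e for e in cohort if e.group == "R"])
    table = build_feature_table([e for e in cohort if e.group != "R"], ref)
    return config, cohort, ref, table
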