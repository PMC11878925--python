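"""Shared fixtures: small synthetic cohorts with planted ground truth.

Everything is generated at test time from fixed seeds; session scope
keeps the heavier cohorts (CNV and program recovery) computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from spathet._utils import KARYOTYPE
from spathet.simulate import (
    CellTypeSpec,
    CloneSpec,
    CohortConfig,
    ProgramSpec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def null_cohort():
    """Single cell type, no clones, no programs: exchangeable observations."""
    return generate_cohort(
        CohortConfig(
            n_sections=1,
            spots_per_section=300,
            n_cells=50,
            n_genes=1200,
            chromosomes=KARYOTYPE[:5],
            cell_types=(CellTypeSpec("tumor", 60, 4.0),),
            tumor_spot_fraction=1.0,
            seed=5,
        )
    )


@pytest.fixture(scope="session")
def gain_cohort():
    """One clone with a whole-chromosome-3 gain at fold 1.5, prevalence
    0.5; chromosomes 1-5 so each carries ~235 genes."""
    return generate_cohort(
        CohortConfig(
            n_sections=1,
            spots_per_section=300,
            n_cells=50,
            n_genes=1200,
            chromosomes=KARYOTYPE[:5],
            clones=(CloneSpec("A", None, (("3", 1.0, "gain", 1.5),), 0.5, None),),
            seed=5,
        )
    )


def make_two_clone_cohort(seed: int):
    """Two clones with disjoint whole-chromosome events covering every
    tumor spot (prevalence 0.5 + 0.5)."""
    return generate_cohort(
        CohortConfig(
            n_sections=1,
            spots_per_section=300,
            n_cells=50,
            n_genes=1200,
            chromosomes=KARYOTYPE[:5],
            clones=(
                CloneSpec("A", None, (("3", 1.0, "gain", 1.5),), 0.5, None),
                CloneSpec("B", None, (("5", 1.0, "loss", 1.5),), 0.5, None),
            ),
            seed=seed,
        )
    )


@pytest.fixture(scope="session")
def two_clone_cohort():
    return make_two_clone_cohort(1)


def make_program_cohort(seed: int):
    """Five samples; three well-separated 50-gene programs active in four
    of them (the cross-sample sharing structure meta-programs require)."""
    secs = tuple(f"section_{i}" for i in range(1, 6))

    def block(s, n):
        return tuple(f"G{i:05d}" for i in range(s, s + n))

    progs = tuple(
        ProgramSpec(f"P{j + 1}", block(700 + 50 * j, 50), secs[:4], 8.0, 0.5)
        for j in range(3)
    )
    return generate_cohort(
        CohortConfig(
            n_sections=5,
            spots_per_section=300,
            n_cells=50,
            n_genes=1000,
            chromosomes=KARYOTYPE[:8],
            programs=progs,
            baseline_mean=1.0,
            seed=seed,
        )
    )


@pytest.fixture(scope="session")
def program_cohort():
    return make_program_cohort(7)


def tumor_obs(cohort, section_index=0):
    cm, _ = cohort.sections[section_index]
    return [o for o in cm.obs_ids if cohort.truth.obs_cell_type[o] == "tumor"]


def stromal_obs(cohort, section_index=0):
    cm, _ = cohort.sections[section_index]
    return [o for o in cm.obs_ids if cohort.truth.obs_cell_type[o] != "tumor"]
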