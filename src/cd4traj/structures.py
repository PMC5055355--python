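"""Fixed-effect design structures for the three trajectory parameters.

Each of intercept / asymptote / log_rate carries one of four fixed-effect
designs: a single overall constant, a sex effect, an age-stratum effect, or
a full age-by-sex interaction.  Designs are coded as cell means (one
coefficient per level), so a coefficient *is* the group-level value of the
parameter for that cell; contrasts between groups are formed downstream
from the coefficient covariance matrix.
"""

from __future__ import annotations

import itertools
from typing import NamedTuple

import numpy as np

__all__ = [
    "AGE_GROUPS",
    "SEXES",
    "DESIGNS",
    "PARAM_NAMES",
    "ModelStructure",
    "PUBLISHED_BEST",
    "enumerate_structures",
]

AGE_GROUPS = ("19-29", "30-39", "40-49", "50-59", "60+")
SEXES = ("female", "male")
DESIGNS = ("constant", "sex", "age", "age_sex")
PARAM_NAMES = ("intercept", "asymptote", "log_rate")

_DESIGN_SIZE = {"constant": 1, "sex": 2, "age": 5, "age_sex": 10}


def design_labels(design: str) -> list[str]:
    """Coefficient level labels for one design, in deterministic order."""
    if design == "constant":
        return ["(all)"]
    if design == "sex":
        return list(SEXES)
    if design == "age":
        return list(AGE_GROUPS)
    if design == "age_sex":
        return [f"{s}:{a}" for s in SEXES for a in AGE_GROUPS]
    raise ValueError(f"unknown design {design!r}")


def design_level(design: str, sex: str, age_group: str) -> int:
    """Index of the coefficient that applies to a (sex, age) cell."""
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age group {age_group!r}")
    if design == "constant":
        return 0
    if design == "sex":
        return SEXES.index(sex)
    if design == "age":
        return AGE_GROUPS.index(age_group)
    if design == "age_sex":
        return SEXES.index(sex) * len(AGE_GROUPS) + AGE_GROUPS.index(age_group)
    raise ValueError(f"unknown design {design!r}")


class ModelStructure(NamedTuple):
    """Which fixed-effect design applies to each trajectory parameter."""

    intercept: str = "constant"
    asymptote: str = "constant"
    log_rate: str = "constant"

    def validate(self) -> "ModelStructure":
        for d in self:
            if d not in DESIGNS:
                raise ValueError(f"unknown design {d!r}; expected one of {DESIGNS}")
        return self

    @property
    def block_sizes(self) -> tuple[int, int, int]:
        return tuple(_DESIGN_SIZE[d] for d in self)

    @property
    def n_fixed(self) -> int:
        """Total number of fixed-effect coefficients (1, 2, 5 or 10 per parameter)."""
        return sum(self.block_sizes)

    @property
    def block_offsets(self) -> tuple[int, int, int]:
        sizes = self.block_sizes
        return (0, sizes[0], sizes[0] + sizes[1])

    def coef_names(self) -> list[str]:
        names = []
        for pname, design in zip(PARAM_NAMES, self):
            names.extend(f"{pname}[{lab}]" for lab in design_labels(design))
        return names

    def coef_index(self, param: str, sex: str, age_group: str) -> int:
        """Global index into the coefficient vector for a parameter and cell."""
        k = PARAM_NAMES.index(param)
        return self.block_offsets[k] + design_level(self[k], sex, age_group)

    def cell_indices(self, sex_arr, age_arr) -> np.ndarray:
        """(n, 3) coefficient indices for arrays of patient sex / age group."""
        n = len(sex_arr)
        out = np.empty((n, 3), dtype=np.intp)
        for j in range(n):
            for k, pname in enumerate(PARAM_NAMES):
                out[j, k] = self.coef_index(pname, sex_arr[j], age_arr[j])
        return out

    def label(self) -> str:
        return "/".join(self)

    @classmethod
    def from_label(cls, label: str) -> "ModelStructure":
        parts = label.split("/")
        if len(parts) != 3:
            raise ValueError(f"expected 'int/asym/rate' label, got {label!r}")
        return cls(*parts).validate()


#: best-supported structure: age-by-sex cells for initial and asymptotic log
#: CD4, age-only effect on the log approach rate.
PUBLISHED_BEST = ModelStructure("age_sex", "age_sex", "age")


def enumerate_structures() -> list[ModelStructure]:
    """All 4^3 = 64 candidate structures, in deterministic order."""
    return [ModelStructure(*combo) for combo in itertools.product(DESIGNS, repeat=3)]
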