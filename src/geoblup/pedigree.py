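"""Father/mother/cross variance-component structure.

The extended covariance model adds Omega = sigma2_f*V_f + sigma2_m*V_m +
sigma2_c*V_c to the polygenic variance, where V_f, V_m, V_c are symmetric
indicator matrices of known constants: entry (i, i') is 1 when individuals
i and i' share the father / mother / cross (father x mother pair), else 0,
with 1 on the diagonal.  Equivalently these are incidence-matrix products
Z_f Z_f' etc. of grouped random effects, which is how prediction of parent
effects for unphenotyped offspring is carried out.  When Omega = 0 the
model collapses to independent polygenic effects.

Unknown parents are treated as unique singleton levels (no sharing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "OmegaDesign", "build_omega_design", "omega_matrix"]

_UNKNOWN = {None, "", "0", "NA", "na", "nan", ".", "unknown"}


def _clean_parent(value, individual: str, tag: str) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return f"__{tag}_unknown_{individual}"
    s = str(value).strip()
    if s in _UNKNOWN:
        return f"__{tag}_unknown_{individual}"
    return s


@dataclass(frozen=True)
class Pedigree:
    """individual -> (father, mother, cross); cross id derived as 'father x mother'."""

    table: pd.DataFrame  # index: individual; columns: father, mother, cross

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a table with columns individual, father, mother."""
        required = {"individual", "father", "mother"}
        if not required.issubset(frame.columns):
            raise ValueError(f"pedigree table needs columns {sorted(required)}")
        rows = {}
        for _, row in frame.iterrows():
            ind = str(row["individual"])
            if ind in rows:
                raise ValueError(f"duplicate pedigree entry for individual {ind!r}")
            father = _clean_parent(row["father"], ind, "f")
            mother = _clean_parent(row["mother"], ind, "m")
            rows[ind] = (father, mother, f"{father}x{mother}")
        table = pd.DataFrame.from_dict(rows, orient="index", columns=["father", "mother", "cross"])
        table.index.name = "individual"
        return cls(table)

    @classmethod
    def read_csv(cls, path, sep: str = ",") -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, sep=sep, dtype=str))

    def levels(self, ids, column: str) -> pd.Series:
        missing = [i for i in ids if i not in self.table.index]
        if missing:
            raise KeyError(f"individuals missing from pedigree: {missing[:5]}")
        return self.table.loc[list(ids), column]


@dataclass(frozen=True)
class OmegaDesign:
    """Indicator matrices (and their incidence factors) for one id ordering."""

    ids: tuple[str, ...]
    V_f: np.ndarray
    V_m: np.ndarray
    V_c: np.ndarray
    Z_f: np.ndarray  # n x n_father incidence (one-hot)
    Z_m: np.ndarray
    Z_c: np.ndarray
    father_levels: tuple[str, ...]
    mother_levels: tuple[str, ...]
    cross_levels: tuple[str, ...]


def _incidence(labels: pd.Series) -> tuple[np.ndarray, tuple[str, ...]]:
    levels = tuple(dict.fromkeys(labels))  # stable order of first appearance
    index = {l: j for j, l in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels):
        Z[i, index[lab]] = 1.0
    return Z, levels


def build_omega_design(ped: Pedigree, ids) -> OmegaDesign:
    """Indicator matrices V_f, V_m, V_c for the individuals in ``ids`` order."""
    ids = tuple(str(i) for i in ids)
    fathers = ped.levels(ids, "father")
    mothers = ped.levels(ids, "mother")
    crosses = ped.levels(ids, "cross")
    Z_f, f_levels = _incidence(fathers)
    Z_m, m_levels = _incidence(mothers)
    Z_c, c_levels = _incidence(crosses)
    return OmegaDesign(
        ids=ids,
        V_f=Z_f @ Z_f.T,
        V_m=Z_m @ Z_m.T,
        V_c=Z_c @ Z_c.T,
        Z_f=Z_f,
        Z_m=Z_m,
        Z_c=Z_c,
        father_levels=f_levels,
        mother_levels=m_levels,
        cross_levels=c_levels,
    )


def omega_matrix(sigma2_f: float, sigma2_m: float, sigma2_c: float,
                 design: OmegaDesign) -> np.ndarray:
    """Omega = sigma2_f*V_f + sigma2_m*V_m + sigma2_c*V_c (zero matrix when all are 0)."""
    for name, v in (("sigma2_f", sigma2_f), ("sigma2_m", sigma2_m), ("sigma2_c", sigma2_c)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    return sigma2_f * design.V_f + sigma2_m * design.V_m + sigma2_c * design.V_c
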