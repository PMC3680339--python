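"""Animal-model BLUP and deregression of estimated breeding values.

The animal model is  y = Xb + Zu + e  with u ~ N(0, A sigma2_a) and
e ~ N(0, I sigma2_e).  With the variance ratio lambda = sigma2_e/sigma2_a
treated as known, Henderson's mixed-model equations are

    | X'X      X'Z          | | b |   | X'y |
    | Z'X      Z'Z + Ainv*l | | u | = | Z'y |

and the prediction error variance (PEV) of each EBV is the corresponding
diagonal of the inverted coefficient matrix times sigma2_e.  Accuracy is
r = sqrt(1 - PEV / sigma2_a).

Deregression removes from each EBV the shrinkage toward, and the
contribution of, the parent average, producing a pseudo-phenotype (dEBV)
suitable as the response of a marker association analysis, together with a
per-animal information weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, build_a_inverse

__all__ = [
    "ConstraintError",
    "AnimalModelDesign",
    "BreedingValueSet",
    "DeregressedSet",
    "solve_animal_model",
    "deregress_ebv",
    "deregression_weight",
]


class ConstraintError(ValueError):
    """Fixed-effect design is singular after reference-level constraints."""


@dataclass
class AnimalModelDesign:
    """Fixed-effect specification for the animal model.

    ``factors`` are categorical columns of the phenotype table (each gets a
    reference-level constraint: the first observed level is dropped);
    ``covariates`` enter as linear regressions; an intercept is always
    included.
    """

    factors: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    animal_col: str = "animal"
    value_col: str = "phenotype"


@dataclass
class BreedingValueSet:
    """Per-animal EBVs with PEV-based accuracies and the variances used."""

    table: pd.DataFrame  # columns: animal, ebv, pev, accuracy
    sigma_a: float
    sigma_e: float

    @property
    def heritability(self) -> float:
        return self.sigma_a / (self.sigma_a + self.sigma_e)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class DeregressedSet:
    """Deregressed EBVs with reliabilities and information weights.

    ``table`` columns: animal, debv, reliability (of the dEBV), weight,
    excluded (bool; True when the EBV reliability fell below the floor).
    """

    table: pd.DataFrame
    heritability: float
    c: float

    def included(self) -> pd.DataFrame:
        return self.table[~self.table["excluded"]].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _design_matrix(df: pd.DataFrame, design: AnimalModelDesign) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in design.factors:
        levels = pd.unique(df[f].astype(str))
        for lev in levels[1:]:  # reference-level constraint: drop first level
            cols.append((df[f].astype(str) == lev).to_numpy(float))
            names.append(f"{f}[{lev}]")
    for c in design.covariates:
        v = df[c].to_numpy(float)
        cols.append(v - v.mean())
        names.append(c)
    X = np.column_stack(cols)
    # identify a factor responsible for any remaining rank deficiency
    if np.linalg.matrix_rank(X) < X.shape[1]:
        r, k = 1, 1
        for f in design.factors:
            nf = sum(1 for nm in names if nm.startswith(f"{f}["))
            k += nf
            rk = np.linalg.matrix_rank(X[:, :k])
            if rk < k:
                raise ConstraintError(
                    f"fixed-effect factor {f!r} is confounded with preceding "
                    "effects; merge levels or drop the factor"
                )
            r = rk
        raise ConstraintError("fixed-effect design is rank deficient")
    return X, names


def solve_animal_model(
    phenotypes: pd.DataFrame,
    design: AnimalModelDesign,
    pedigree: Pedigree,
    variance_ratio: float,
    sigma_a: float = 1.0,
) -> BreedingValueSet:
    """Solve the mixed-model equations for EBVs and PEV-based accuracies.

    Parameters
    ----------
    phenotypes
        One row per record; must contain ``design.animal_col``,
        ``design.value_col`` and every design factor/covariate.
    variance_ratio
        lambda = sigma2_e / sigma2_a, e.g. (1 - h2)/h2 = 5.25 for h2 = 0.16.
    sigma_a
        Additive variance in trait units; scales reported PEV (accuracies
        depend only on the ratio).

    Returns EBVs for *all* pedigree animals, phenotyped or not.
    """
    if variance_ratio <= 0:
        raise ValueError("variance_ratio must be positive")
    df = phenotypes.reset_index(drop=True)
    missing = [a for a in df[design.animal_col].astype(str) if a not in pedigree]
    if missing:
        raise KeyError(f"phenotyped animals not in pedigree: {missing[:5]}")

    n_anim = len(pedigree)
    y = df[design.value_col].to_numpy(float)
    X, names = _design_matrix(df, design)
    nfix = X.shape[1]
    rec_anim = np.array([pedigree.index_of(a) for a in df[design.animal_col].astype(str)])

    # Z'Z is diagonal (counts); assemble dense MME (desk-scale pedigrees)
    Ainv = build_a_inverse(pedigree).toarray()
    XtX = X.T @ X
    XtZ = np.zeros((nfix, n_anim))
    np.add.at(XtZ.T, rec_anim, X)
    ZtZ = np.zeros(n_anim)
    np.add.at(ZtZ, rec_anim, 1.0)
    Zty = np.zeros(n_anim)
    np.add.at(Zty, rec_anim, y)

    C = np.zeros((nfix + n_anim, nfix + n_anim))
    C[:nfix, :nfix] = XtX
    C[:nfix, nfix:] = XtZ
    C[nfix:, :nfix] = XtZ.T
    C[nfix:, nfix:] = variance_ratio * Ainv
    C[nfix + np.arange(n_anim), nfix + np.arange(n_anim)] += ZtZ
    rhs = np.concatenate([X.T @ y, Zty])

    Cinv = np.linalg.inv(C)
    sol = Cinv @ rhs
    u = sol[nfix:]
    sigma_e = variance_ratio * sigma_a
    pev = np.diag(Cinv)[nfix:] * sigma_e
    rel = np.clip(1.0 - pev / sigma_a, 0.0, 1.0)
    table = pd.DataFrame(
        {
            "animal": list(pedigree.ids),
            "ebv": u,
            "pev": pev,
            "accuracy": np.sqrt(rel),
        }
    )
    return BreedingValueSet(table=table, sigma_a=sigma_a, sigma_e=sigma_e)


# ---------------------------------------------------------------------------
# deregression


def deregression_weight(reliability: float, heritability: float, c: float) -> float:
    """Information weight w = (1 - h2) / ((c + (1 - r2)/r2) * h2).

    ``reliability`` is the reliability r2 of the deregressed proof; ``c`` is
    the fraction of genetic variance not captured by the markers.
    """
    r2 = reliability
    if r2 <= 0:
        raise ValueError("reliability must be positive for a weight")
    return (1.0 - heritability) / ((c + (1.0 - r2) / r2) * heritability)


def _effective_records(r2_i: float, r2_pa: float, lam: float) -> tuple[float, float]:
    """Effective record counts (Z'Z_pa, Z'Z_i) of the 2x2 information system.

    The individual's EBV blends own information with the parent average.
    Modelling the pair (g_pa, g_i) with relationship matrix
    [[1/2, 1/2], [1/2, 1]] gives the 2x2 mixed-model equations

        | z_pa + 4 lam   -2 lam        | — whose inverse times sigma2_e is
        | -2 lam          z_i + 2 lam  |   the PEV of (PA, EBV).

    Setting the implied reliabilities equal to (r2_pa, r2_i) and solving
    yields, with v = z_i + 2 lam:

        (1 - r2_i) v^2 - lam v - 2 lam^2 (1 - r2_pa) = 0
        z_pa = 2 v (1 - r2_i) / (1 - r2_pa) - 4 lam
    """
    disc = 1.0 + 8.0 * (1.0 - r2_pa) * (1.0 - r2_i)
    v = lam * (1.0 + np.sqrt(disc)) / (2.0 * (1.0 - r2_i))
    z_i = v - 2.0 * lam
    # z_pa may be negative when the stated parent-average reliability is
    # lower than what the individual's own information already implies; the
    # exact solution is kept (clamping would distort the deregression)
    z_pa = 2.0 * v * (1.0 - r2_i) / (1.0 - r2_pa) - 4.0 * lam
    return z_pa, z_i


def deregress_ebv(
    bvs: BreedingValueSet,
    pedigree: Pedigree,
    c: float = 0.5,
    heritability: float | None = None,
    reliability_floor: float = 0.1,
    mode: str = "full",
    animals=None,
) -> DeregressedSet:
    """Deregress EBVs to pseudo-phenotypes with information weights.

    ``mode='full'`` removes the parent-average contribution by solving the
    2x2 information system for the parent average and the individual; the
    deregressed proof is the individual's right-hand side divided by its
    effective record count, and its reliability is z_i / (z_i + lambda).
    ``mode='simple'`` is the textbook dEBV = EBV / r2.  Animals whose EBV
    reliability is below ``reliability_floor`` are flagged excluded.  When
    both parents are unknown the full mode coincides with the simple mode
    (the parent average carries no information of its own).
    """
    if mode not in {"full", "simple"}:
        raise ValueError(f"unknown mode {mode!r}")
    h2 = bvs.heritability if heritability is None else heritability
    lam = (1.0 - h2) / h2
    tab = bvs.table.set_index("animal")
    ids = [str(a) for a in (animals if animals is not None else bvs.table["animal"])]

    rows = []
    for a in ids:
        ebv = float(tab.at[a, "ebv"])
        r2 = float(tab.at[a, "accuracy"]) ** 2
        if r2 <= reliability_floor:
            rows.append((a, np.nan, np.nan, np.nan, True))
            continue
        si = pedigree.sire_idx[pedigree.index_of(a)]
        di = pedigree.dam_idx[pedigree.index_of(a)]

        def _parent(i):
            if i < 0:
                return 0.0, 0.0
            pid = pedigree.ids[i]
            return float(tab.at[pid, "ebv"]), float(tab.at[pid, "accuracy"]) ** 2

        ebv_s, r2_s = _parent(si)
        ebv_d, r2_d = _parent(di)
        # reliability of the parent average *on the scale of its own
        # variance* (var(PA) = sigma2_a/2): var(PA_hat)/(sigma2_a/2)
        # = (r2_s + r2_d)/2.  (The familiar (r2_s + r2_d)/4 measures the
        # same information against the full sigma2_a.)
        r2_pa = min((r2_s + r2_d) / 2.0, 1.0 - 1e-9)

        if mode == "simple" or (si < 0 and di < 0) or r2_pa <= 0:
            debv = ebv / r2
            # reliability of own information net of the parent average:
            # z_i/(z_i + lam) with z_i from r2 alone
            z_i = lam * r2 / (1.0 - r2)
            rel_d = r2
        else:
            pa = 0.5 * (ebv_s + ebv_d)
            z_pa, z_i = _effective_records(r2, r2_pa, lam)
            if z_i <= 0:
                rows.append((a, np.nan, np.nan, np.nan, True))
                continue
            # RHS of the individual's equation, then divide out its record count
            y_i = -2.0 * lam * pa + (z_i + 2.0 * lam) * ebv
            debv = y_i / z_i
            rel_d = z_i / (z_i + lam)
        w = deregression_weight(rel_d, h2, c)
        rows.append((a, debv, rel_d, w, False))

    table = pd.DataFrame(
        rows, columns=["animal", "debv", "reliability", "weight", "excluded"]
    )
    n_exc = int(table["excluded"].sum())
    if n_exc:
        warnings.warn(
            f"{n_exc} animals excluded from deregression "
            f"(reliability <= {reliability_floor})",
            stacklevel=2,
        )
    return DeregressedSet(table=table, heritability=h2, c=c)
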