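"""Genetic parameters for the ten-trait dairy breeding goal.

The goal comprises eight routinely evaluated traits — fat yield (FY), protein
yield (PY), body condition score (BCS), stature (STAT), age at first service
(AFS), interval from first service to conception (FSTC), clinical ketosis (CK)
and displaced abomasum (DA) — plus the two feed-efficiency candidates: dry
matter intake (DMI) and residual feed intake (RFI).

This module houses the per-trait parameters (genetic and phenotypic standard
deviations, heritability, GEBV accuracy, favourable direction), the paired
genetic/phenotypic correlation matrices with standard errors for the
feed-efficiency rows, and the transformations the index machinery needs:
standard-error shrinkage toward zero, nearest-positive-definite repair by
eigenvalue clipping, and correlation/covariance conversion.

Only the DMI and RFI rows of the correlation matrices are observed; the
remaining core-trait block must be filled synthetically (see
:mod:`feedsel.synthetic_data`) before the matrices are complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

TRAIT_ORDER: tuple[str, ...] = (
    "FY", "PY", "BCS", "STAT", "AFS", "FSTC", "CK", "DA", "DMI", "RFI",
)
NOVEL_TRAITS: tuple[str, ...] = ("DMI", "RFI")

#: tolerance for the h2 vs (sigma_g/sigma_p)^2 consistency check; printed
#: parameters are rounded to 2 decimals.
H2_CONSISTENCY_TOL = 0.02

PROVENANCE_PRINTED = "printed"
PROVENANCE_SYNTHETIC = "synthetic"
PROVENANCE_REQUIRED = "synthetic-required"


class ParameterError(ValueError):
    """Raised for invalid or inconsistent genetic parameters."""


@dataclass(frozen=True)
class Trait:
    """A trait in the breeding goal.

    ``favorable_direction`` is +1 when an increase is desirable (production,
    intake under the positive-pressure convention) and -1 when a decrease is
    desirable (fertility intervals, disease incidence, RFI).
    """

    code: str
    units: str
    favorable_direction: int

    def __post_init__(self) -> None:
        if self.code not in TRAIT_ORDER:
            raise ParameterError(f"unknown trait code {self.code!r}")
        if self.favorable_direction not in (+1, -1):
            raise ParameterError("favorable_direction must be +1 or -1")


@dataclass(frozen=True)
class TraitParams:
    """Per-trait genetic parameters (trait units)."""

    trait: Trait
    sigma_g: float
    sigma_p: float
    h2: float
    r_gebv: float

    def __post_init__(self) -> None:
        if not (0 < self.sigma_g <= self.sigma_p):
            raise ParameterError(
                f"{self.trait.code}: need 0 < sigma_g <= sigma_p, "
                f"got {self.sigma_g}, {self.sigma_p}"
            )
        if not (0 < self.h2 < 1):
            raise ParameterError(f"{self.trait.code}: h2 must lie in (0,1)")
        if not (0 < self.r_gebv <= 1):
            raise ParameterError(f"{self.trait.code}: r_gebv must lie in (0,1]")

    @property
    def h2_implied(self) -> float:
        """Heritability implied by the variance ratio (sigma_g/sigma_p)^2."""
        return (self.sigma_g / self.sigma_p) ** 2

    def check_consistency(self, tol: float = H2_CONSISTENCY_TOL,
                          strict: bool = False) -> bool:
        """Check h2 against (sigma_g/sigma_p)^2 within ``tol``.

        Printed parameter tables are not always internally consistent (the
        sigmas and h2 can come from different models or scales); by default an
        inconsistency triggers a warning and returns False, while
        ``strict=True`` raises.
        """
        ok = abs(self.h2 - self.h2_implied) <= tol
        if not ok:
            msg = (
                f"{self.trait.code}: h2 {self.h2:.2f} vs implied "
                f"(sigma_g/sigma_p)^2 = {self.h2_implied:.2f} differ by more "
                f"than {tol}"
            )
            if strict:
                raise ParameterError(msg)
            warnings.warn(msg, stacklevel=2)
        return ok


@dataclass
class CorrelationSet:
    """Paired genetic (rg) and phenotypic (rp) correlation matrices.

    Matrices are pandas DataFrames indexed by trait code in ``TRAIT_ORDER``.
    ``se_rg``/``se_rp`` hold standard errors (NaN where unavailable) and
    ``provenance_g``/``provenance_p`` record, per cell, whether the value was
    printed in the source table, generated synthetically, or still awaits a
    synthetic fill ("synthetic-required").
    """

    rg: pd.DataFrame
    rp: pd.DataFrame
    se_rg: pd.DataFrame
    se_rp: pd.DataFrame
    provenance_g: pd.DataFrame
    provenance_p: pd.DataFrame

    def copy(self) -> "CorrelationSet":
        return CorrelationSet(*(m.copy() for m in (
            self.rg, self.rp, self.se_rg, self.se_rp,
            self.provenance_g, self.provenance_p)))

    @property
    def traits(self) -> list[str]:
        return list(self.rg.index)

    def is_complete(self) -> bool:
        """True when no cell is still flagged synthetic-required."""
        return not (
            (self.provenance_g == PROVENANCE_REQUIRED).any().any()
            or (self.provenance_p == PROVENANCE_REQUIRED).any().any()
        )

    def validate(self, eig_floor: float | None = None) -> None:
        """Check symmetry, unit diagonal, [-1, 1] range and (optionally) a
        minimum-eigenvalue floor on both matrices."""
        for name, m in (("rg", self.rg), ("rp", self.rp)):
            a = m.to_numpy(dtype=float)
            if not np.allclose(a, a.T, atol=1e-12):
                raise ParameterError(f"{name} is not symmetric")
            if not np.allclose(np.diag(a), 1.0, atol=1e-12):
                raise ParameterError(f"{name} diagonal is not 1")
            if np.nanmax(np.abs(a)) > 1 + 1e-12:
                raise ParameterError(f"{name} has entries outside [-1, 1]")
            if eig_floor is not None:
                lam = np.linalg.eigvalsh(np.nan_to_num(a))
                if lam.min() < eig_floor:
                    raise ParameterError(
                        f"{name} min eigenvalue {lam.min():.3e} below floor"
                    )


def _data_path(name: str) -> Path:
    return Path(str(resources.files("feedsel").joinpath("data", name)))


def default_fixture_dir() -> Path:
    """Directory with the packaged parameter fixtures."""
    return _data_path("trait_params.csv").parent


def load_parameter_fixtures(
    fixture_path: str | Path | None = None,
    consistency: str = "warn",
) -> tuple[list[TraitParams], CorrelationSet]:
    """Load trait parameters and printed correlations from CSV fixtures.

    ``fixture_path`` is a directory containing ``trait_params.csv`` (header
    ``trait,sigma_g,sigma_p,h2,r_gebv,direction,units``) and
    ``correlations.csv`` (long format
    ``trait_a,trait_b,kind{g|p},value,se,provenance``); by default the
    packaged copies of the printed tables are used.

    Returns the ten :class:`TraitParams` in goal order and a
    :class:`CorrelationSet` whose observed feed-efficiency cells carry
    provenance "printed" and whose unobserved core-trait off-diagonals are
    flagged "synthetic-required".

    ``consistency`` governs the h2 vs (sigma_g/sigma_p)^2 check: "warn"
    (default), "strict" (raise) or "ignore". Printed core-trait rows are
    known to fail it (their sigmas and h2 come from different models).
    """
    if consistency not in ("warn", "strict", "ignore"):
        raise ValueError("consistency must be 'warn', 'strict' or 'ignore'")
    base = Path(fixture_path) if fixture_path is not None else default_fixture_dir()
    tp_file = base / "trait_params.csv"
    corr_file = base / "correlations.csv"
    if not tp_file.exists():
        raise FileNotFoundError(tp_file)
    tp = pd.read_csv(tp_file)

    missing = set(TRAIT_ORDER) - set(tp["trait"])
    if missing:
        raise ParameterError(f"missing trait rows: {sorted(missing)}")

    params: list[TraitParams] = []
    for code in TRAIT_ORDER:
        row = tp.loc[tp["trait"] == code].iloc[0]
        p = TraitParams(
            trait=Trait(code=code, units=str(row["units"]),
                        favorable_direction=int(row["direction"])),
            sigma_g=float(row["sigma_g"]),
            sigma_p=float(row["sigma_p"]),
            h2=float(row["h2"]),
            r_gebv=float(row["r_gebv"]),
        )
        if consistency != "ignore":
            p.check_consistency(strict=consistency == "strict")
        params.append(p)

    corr = _empty_correlation_set()
    long = pd.read_csv(corr_file)
    for _, row in long.iterrows():
        a, b, kind = row["trait_a"], row["trait_b"], row["kind"]
        if a not in TRAIT_ORDER or b not in TRAIT_ORDER:
            raise ParameterError(f"unknown trait pair ({a}, {b})")
        value, se = float(row["value"]), float(row["se"])
        if not -1 <= value <= 1:
            raise ParameterError(f"correlation ({a},{b},{kind}) outside [-1,1]")
        if se < 0:
            raise ParameterError(f"negative SE for ({a},{b},{kind})")
        mat, semat, prov = {
            "g": (corr.rg, corr.se_rg, corr.provenance_g),
            "p": (corr.rp, corr.se_rp, corr.provenance_p),
        }[str(kind)]
        for i, j in ((a, b), (b, a)):
            mat.loc[i, j] = value
            semat.loc[i, j] = se
            prov.loc[i, j] = str(row["provenance"])
    return params, corr


def _empty_correlation_set() -> CorrelationSet:
    idx = list(TRAIT_ORDER)
    eye = pd.DataFrame(np.eye(10), index=idx, columns=idx)
    nan = pd.DataFrame(np.nan, index=idx, columns=idx)
    prov = pd.DataFrame(PROVENANCE_REQUIRED, index=idx, columns=idx)
    for t in idx:
        prov.loc[t, t] = PROVENANCE_PRINTED
    return CorrelationSet(
        rg=eye.copy(), rp=eye.copy(),
        se_rg=nan.copy(), se_rp=nan.copy(),
        provenance_g=prov.copy(), provenance_p=prov.copy(),
    )


def shrink_toward_zero(
    corr: CorrelationSet,
    which: str = "both",
    traits: tuple[str, ...] = NOVEL_TRAITS,
) -> CorrelationSet:
    """Move each observed feed-efficiency correlation toward zero by its SE.

    This is the conservative-parameter variant of the selection scenarios: a
    correlation of -0.61 with SE 0.17 becomes -0.44; shrinkage never crosses
    zero (0.05 with SE 0.13 clamps to 0). Cells without an SE (the synthetic
    core block) are untouched. ``which`` selects "g", "p" or "both" matrices.
    """
    if which not in ("g", "p", "both"):
        raise ValueError("which must be 'g', 'p' or 'both'")
    out = corr.copy()
    targets = []
    if which in ("g", "both"):
        targets.append((out.rg, out.se_rg))
    if which in ("p", "both"):
        targets.append((out.rp, out.se_rp))
    for mat, semat in targets:
        done: set[frozenset] = set()
        for a in traits:
            for b in mat.columns:
                if a == b or frozenset((a, b)) in done:
                    continue
                done.add(frozenset((a, b)))
                se = semat.loc[a, b]
                if pd.isna(se):
                    continue
                if se < 0:
                    raise ParameterError(f"negative SE for ({a},{b})")
                v = mat.loc[a, b]
                shrunk = np.sign(v) * max(0.0, abs(v) - se)
                mat.loc[a, b] = shrunk
                mat.loc[b, a] = shrunk
    return out


def nearest_pd_repair(
    matrix: np.ndarray | pd.DataFrame,
    floor: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray | pd.DataFrame:
    """Repair a symmetric correlation matrix to be positive definite.

    Eigenvalues below ``floor`` are clipped up to it and the diagonal is
    renormalised to 1; the two steps alternate until the floor holds, which
    makes the operation an exact fixed point on already-valid matrices (and
    hence idempotent). DataFrame input preserves its labels.
    """
    labels = None
    if isinstance(matrix, pd.DataFrame):
        labels = (matrix.index, matrix.columns)
        matrix = matrix.to_numpy(dtype=float)
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ParameterError("input must be square")
    if not np.allclose(a, a.T, atol=1e-8):
        raise ParameterError("input must be symmetric")
    a = (a + a.T) / 2.0

    for _ in range(max_iter):
        lam, q = np.linalg.eigh(a)
        if lam.min() >= floor and np.allclose(np.diag(a), 1.0, atol=1e-12):
            break
        lam = np.clip(lam, floor, None)
        a = (q * lam) @ q.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 1.0)
    else:
        raise ParameterError("PD repair did not converge")

    if labels is not None:
        return pd.DataFrame(a, index=labels[0], columns=labels[1])
    return a


def correlation_to_covariance(
    corr: np.ndarray | pd.DataFrame, sds: np.ndarray
) -> np.ndarray | pd.DataFrame:
    """cov[i, j] = corr[i, j] * sd_i * sd_j."""
    sds = np.asarray(sds, dtype=float)
    c = corr.to_numpy(dtype=float) if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    if c.shape != (sds.size, sds.size):
        raise ParameterError(
            f"dimension mismatch: corr {c.shape} vs {sds.size} sds")
    if np.any(sds <= 0):
        raise ParameterError("standard deviations must be positive")
    cov = c * np.outer(sds, sds)
    if isinstance(corr, pd.DataFrame):
        return pd.DataFrame(cov, index=corr.index, columns=corr.columns)
    return cov


def covariance_to_correlation(
    cov: np.ndarray | pd.DataFrame,
) -> np.ndarray | pd.DataFrame:
    """Inverse of :func:`correlation_to_covariance`."""
    c = cov.to_numpy(dtype=float) if isinstance(cov, pd.DataFrame) else np.asarray(cov, float)
    d = np.sqrt(np.diag(c))
    if np.any(d <= 0):
        raise ParameterError("covariance diagonal must be positive")
    corr = c / np.outer(d, d)
    if isinstance(cov, pd.DataFrame):
        return pd.DataFrame(corr, index=cov.index, columns=cov.columns)
    return corr


def sigma_g_vector(params: list[TraitParams]) -> np.ndarray:
    return np.array([p.sigma_g for p in params])


def sigma_p_vector(params: list[TraitParams]) -> np.ndarray:
    return np.array([p.sigma_p for p in params])


def accuracy_vector(params: list[TraitParams]) -> np.ndarray:
    return np.array([p.r_gebv for p in params])
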