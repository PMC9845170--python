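"""Power-law mass calibration: m = η · σ^{3/2}.

An insect's optical extinction cross section σ (mm²) tracks the
geometrical cross section of its body, whose 3/2 power tracks body
volume, whose product with a volumetric mass density gives mass. Treating
the shape factor, the quasi-ballistic transmittance and the volumetric
mass density as constant across species collapses the chain into a
single-coefficient power law with exponent 3/2. η (mg/mm³) absorbs all
three constants and is fitted to weighed specimens by damped
(Levenberg–Marquardt) least squares; the published field calibration
gives η = 0.157 for wet mass and η = 0.075 for dry mass.

The module follows a model/results layout: build a
:class:`MassCalibration` from calibration samples (or arrays), call
``fit()`` and read estimates and diagnostics off the returned
:class:`MassCalibrationResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MassModel",
    "MassCalibration",
    "MassCalibrationResults",
    "fit_eta",
    "predict_mass",
    "published_constants",
    "closed_form_eta",
    "PUBLISHED_ETA_WET",
    "PUBLISHED_ETA_DRY",
]

Basis = Literal["wet", "dry"]

#: Published calibration coefficients (mg/mm³) and their adjusted R².
PUBLISHED_ETA_WET = 0.157
PUBLISHED_ETA_DRY = 0.075
PUBLISHED_R2_ADJ = {"wet": 0.96, "dry": 0.98}

EXPONENT = 1.5


@dataclass(frozen=True)
class MassModel:
    """A calibrated mass law m = η·σ^{3/2} for one mass basis.

    The physical constants behind η — volumetric mass density, body shape
    factor, quasi-ballistic transmittance — are not separately
    identifiable from (σ, m) pairs; only their combination η is.
    """

    eta: float  # mg / mm³
    basis: Basis
    r2_adj: float | None = None
    n_samples: int | None = None
    source: str = "fit"

    def __post_init__(self) -> None:
        if not (self.eta > 0):
            raise ValueError("eta must be positive")

    @property
    def exponent(self) -> float:
        return EXPONENT

    def predict(self, sigma) -> np.ndarray | float:
        """Predicted mass (mg) for cross section(s) σ in mm²."""
        sigma_arr = np.asarray(sigma, dtype=float)
        if np.any(sigma_arr < 0):
            raise ValueError("sigma must be non-negative")
        out = self.eta * sigma_arr**EXPONENT
        return float(out) if np.isscalar(sigma) or out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "eta": self.eta,
            "basis": self.basis,
            "exponent": EXPONENT,
            "r2_adj": self.r2_adj,
            "n_samples": self.n_samples,
            "source": self.source,
        }


def published_constants(basis: Basis) -> MassModel:
    """The published field calibration for the requested mass basis."""
    if basis == "wet":
        eta = PUBLISHED_ETA_WET
    elif basis == "dry":
        eta = PUBLISHED_ETA_DRY
    else:
        raise ValueError("basis must be 'wet' or 'dry'")
    return MassModel(
        eta=eta, basis=basis, r2_adj=PUBLISHED_R2_ADJ[basis], source="published"
    )


def predict_mass(sigma, model: MassModel) -> np.ndarray | float:
    """Functional alias for :meth:`MassModel.predict`."""
    return model.predict(sigma)


def closed_form_eta(
    sigma: np.ndarray, mass: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Exact least-squares solution for the one-parameter power law.

    Because the model is linear in η, minimising Σ w (m − η σ^{3/2})²
    has the closed form η = Σ w m σ^{3/2} / Σ w σ³. Serves as the
    independent oracle for the iterative fit.
    """
    x = np.asarray(sigma, dtype=float) ** EXPONENT
    m = np.asarray(mass, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    denom = np.sum(w * x * x)
    if denom == 0:
        raise ValueError("all cross sections are zero; fit is singular")
    return float(np.sum(w * m * x) / denom)


class MassCalibration:
    """Mass-calibration model over a set of weighed specimens.

    Parameters
    ----------
    sigma : array-like
        Body extinction cross sections, mm².
    mass : array-like
        Specimen masses, mg, on the chosen basis.
    basis : {'wet', 'dry'}
    groups : sequence of str, optional
        Per-specimen group labels; enables the group-mean fitting mode.
    """

    def __init__(self, sigma, mass, basis: Basis = "dry", groups=None):
        self.sigma = np.asarray(sigma, dtype=float)
        self.mass = np.asarray(mass, dtype=float)
        if self.sigma.shape != self.mass.shape or self.sigma.ndim != 1:
            raise ValueError("sigma and mass must be 1-D arrays of equal length")
        if self.sigma.size < 2:
            raise ValueError("need at least two calibration samples")
        if np.any(self.sigma <= 0) or np.any(self.mass <= 0):
            raise ValueError("cross sections and masses must be positive")
        if basis not in ("wet", "dry"):
            raise ValueError("basis must be 'wet' or 'dry'")
        self.basis: Basis = basis
        self.groups = None if groups is None else np.asarray(groups, dtype=object)

    @classmethod
    def from_samples(cls, samples: Sequence, basis: Basis = "dry") -> "MassCalibration":
        """Build from :class:`~ebossflux.io.CalibrationSample` records."""
        sigma = [s.sigma for s in samples]
        mass = [s.mass_wet if basis == "wet" else s.mass_dry for s in samples]
        groups = [s.group for s in samples]
        return cls(sigma, mass, basis=basis, groups=groups)

    def fit(
        self,
        *,
        method: str = "lm",
        mode: str = "per_specimen",
        free_exponent: bool = False,
    ) -> "MassCalibrationResults":
        """Fit η by damped least squares.

        ``mode='group_mean'`` fits the per-group mean points weighted by
        group size (requires group labels). ``free_exponent=True`` also
        frees the exponent — a diagnostic for checking the 3/2 law, never
        used by the pipeline.
        """
        if mode == "per_specimen":
            sig, m, w = self.sigma, self.mass, np.ones_like(self.sigma)
        elif mode == "group_mean":
            if self.groups is None:
                raise ValueError("group_mean mode requires group labels")
            sig_l, m_l, w_l = [], [], []
            for g in dict.fromkeys(self.groups):  # preserves order
                mask = self.groups == g
                sig_l.append(self.sigma[mask].mean())
                m_l.append(self.mass[mask].mean())
                w_l.append(mask.sum())
            sig, m, w = map(np.asarray, (sig_l, m_l, w_l))
        else:
            raise ValueError(f"unknown mode {mode!r}")

        if np.allclose(sig, 0):
            raise ValueError("all cross sections zero; fit is singular")

        sw = np.sqrt(w)
        if free_exponent:
            x0 = np.array([closed_form_eta(sig, m, w), EXPONENT])

            def resid(p):
                return sw * (m - p[0] * sig ** p[1])

        else:
            x0 = np.array([closed_form_eta(sig, m, w)])

            def resid(p):
                return sw * (m - p[0] * sig**EXPONENT)

        if method == "lm":
            sol = least_squares(resid, x0, method="lm")
            params = sol.x
        elif method == "closed_form":
            if free_exponent:
                raise ValueError("closed_form applies to the fixed-exponent model")
            params = np.array([closed_form_eta(sig, m, w)])
        else:
            raise ValueError(f"unknown method {method!r}")

        eta = float(params[0])
        exponent = float(params[1]) if free_exponent else EXPONENT
        fitted = eta * sig**exponent
        resid_v = sw * (m - fitted)
        n, p = sig.size, (2 if free_exponent else 1)
        ss_res = float(np.sum(resid_v**2))
        m_bar = float(np.sum(w * m) / np.sum(w))
        ss_tot = float(np.sum(w * (m - m_bar) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        r2_adj = (
            1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else float("nan")
        )
        # Gauss-Newton standard error for the (locally) linear parameter
        jac = sw[:, None] * np.column_stack(
            [sig**exponent]
            + ([eta * sig**exponent * np.log(sig)] if free_exponent else [])
        )
        dof = max(n - p, 1)
        s2 = ss_res / dof
        try:
            cov = s2 * np.linalg.inv(jac.T @ jac)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            bse = np.full(p, np.nan)

        return MassCalibrationResults(
            model=self,
            eta=eta,
            exponent=exponent,
            free_exponent=free_exponent,
            eta_stderr=float(bse[0]),
            exponent_stderr=float(bse[1]) if free_exponent else 0.0,
            r2=r2,
            r2_adj=r2_adj,
            nobs=n,
            mode=mode,
            method=method,
        )


@dataclass
class MassCalibrationResults:
    """Estimates and diagnostics from :meth:`MassCalibration.fit`."""

    model: MassCalibration
    eta: float
    exponent: float
    free_exponent: bool
    eta_stderr: float
    exponent_stderr: float
    r2: float
    r2_adj: float
    nobs: int
    mode: str
    method: str

    def as_mass_model(self) -> MassModel:
        if self.free_exponent:
            raise ValueError("diagnostic free-exponent fit is not a pipeline model")
        return MassModel(
            eta=self.eta,
            basis=self.model.basis,
            r2_adj=self.r2_adj,
            n_samples=self.nobs,
            source="fit",
        )

    def predict(self, sigma) -> np.ndarray | float:
        sigma_arr = np.asarray(sigma, dtype=float)
        if np.any(sigma_arr < 0):
            raise ValueError("sigma must be non-negative")
        out = self.eta * sigma_arr**self.exponent
        return float(out) if np.isscalar(sigma) or out.ndim == 0 else out

    def summary(self) -> str:
        lines = [
            "Power-law mass calibration  m = eta * sigma^%s" % (
                "b" if self.free_exponent else "3/2"
            ),
            "=" * 54,
            f"basis:        {self.model.basis}",
            f"observations: {self.nobs} ({self.mode}, method={self.method})",
            f"eta:          {self.eta:.4g} mg/mm^3  (SE {self.eta_stderr:.2g})",
        ]
        if self.free_exponent:
            lines.append(
                f"exponent:     {self.exponent:.4g}  (SE {self.exponent_stderr:.2g})"
            )
        lines += [
            f"R^2:          {self.r2:.4f}",
            f"R^2 adj:      {self.r2_adj:.4f}",
        ]
        return "\n".join(lines)


def fit_eta(samples: Sequence, basis: Basis = "dry", **fit_kwargs) -> MassModel:
    """Fit the calibration law to specimen records and return the mass law."""
    res = MassCalibration.from_samples(samples, basis=basis).fit(**fit_kwargs)
    return res.as_mass_model()


def save_models(models: dict[str, MassModel], path: str | Path) -> Path:
    """Persist fitted models (e.g. {'wet': ..., 'dry': ...}) as JSON."""
    path = Path(path)
    payload = {
        f"eta_{basis}": model.to_dict() for basis, model in models.items()
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def load_models(path: str | Path) -> dict[str, MassModel]:
    data = json.loads(Path(path).read_text())
    out = {}
    for key, d in data.items():
        basis = key.removeprefix("eta_")
        out[basis] = MassModel(
            eta=d["eta"],
            basis=d["basis"],
            r2_adj=d.get("r2_adj"),
            n_samples=d.get("n_samples"),
            source=d.get("source", "fit"),
        )
    return out
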