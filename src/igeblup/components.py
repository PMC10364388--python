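"""Variance-component containers shared by the simulator, REML and BLUP.

All (co)variances are on the scale of the analysed phenotype (the
binary score times 100, so variances are in squared score points).
The ``social`` model carries the 2x2 direct-social genetic matrix

    [[sigma2_ud, sigma_uds],
     [sigma_uds, sigma2_us]]

while the ``classical`` model has no social terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

CLASSICAL = "classical"
SOCIAL = "social"


@dataclass
class VarianceComponents:
    """(Co)variance components of the direct / social animal models.

    ``sigma2_us`` and ``sigma_uds`` must be ``None`` for the classical
    model.  ``meta`` holds estimation metadata (iterations, -2logL, AIC)
    when the object comes out of REML rather than a configuration.
    """

    sigma2_ud: float
    sigma2_us: float | None
    sigma_uds: float | None
    sigma2_gr: float
    sigma2_cl: float
    sigma2_cg: float
    sigma2_e: float
    model: str = SOCIAL
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in (CLASSICAL, SOCIAL):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == CLASSICAL:
            if self.sigma2_us is not None or self.sigma_uds is not None:
                raise ValueError("classical model must not carry social terms")
        else:
            if self.sigma2_us is None or self.sigma_uds is None:
                raise ValueError("social model requires sigma2_us and sigma_uds")
        for name in ("sigma2_ud", "sigma2_us", "sigma2_gr", "sigma2_cl",
                     "sigma2_cg", "sigma2_e"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.model == SOCIAL:
            bound = math.sqrt(self.sigma2_ud * self.sigma2_us)
            if abs(self.sigma_uds) > bound + 1e-12:
                raise ValueError(
                    f"|sigma_uds|={abs(self.sigma_uds):.6g} exceeds "
                    f"sqrt(sigma2_ud*sigma2_us)={bound:.6g}"
                )

    @property
    def is_social(self) -> bool:
        return self.model == SOCIAL

    def genetic_matrix(self) -> np.ndarray:
        """2x2 direct-social covariance (1x1 for the classical model)."""
        if self.is_social:
            return np.array(
                [[self.sigma2_ud, self.sigma_uds],
                 [self.sigma_uds, self.sigma2_us]]
            )
        return np.array([[self.sigma2_ud]])

    def r_uds(self) -> float | None:
        if not self.is_social:
            return None
        denom = math.sqrt(self.sigma2_ud * self.sigma2_us)
        return self.sigma_uds / denom if denom > 0 else math.nan

    def as_vector(self) -> np.ndarray:
        """Parameters in estimation order (genetic block first, residual last)."""
        if self.is_social:
            return np.array([
                self.sigma2_ud, self.sigma_uds, self.sigma2_us,
                self.sigma2_gr, self.sigma2_cl, self.sigma2_cg, self.sigma2_e,
            ])
        return np.array([
            self.sigma2_ud, self.sigma2_gr, self.sigma2_cl,
            self.sigma2_cg, self.sigma2_e,
        ])

    @classmethod
    def from_vector(cls, theta, model: str, meta: dict | None = None):
        theta = [float(t) for t in theta]
        if model == SOCIAL:
            ud, uds, us, gr, cl, cg, e = theta
            return cls(ud, us, uds, gr, cl, cg, e, model=model, meta=meta or {})
        ud, gr, cl, cg, e = theta
        return cls(ud, None, None, gr, cl, cg, e, model=model, meta=meta or {})

    @property
    def n_params(self) -> int:
        """Number of estimated (co)variance parameters (7 social, 5 classical)."""
        return 7 if self.is_social else 5

    def with_(self, **changes) -> "VarianceComponents":
        return replace(self, **changes)


def social_components(
    sigma2_ud: float,
    sigma2_us: float,
    sigma2_gr: float,
    sigma2_cl: float,
    sigma2_cg: float,
    sigma2_e: float,
    r_uds: float,
) -> VarianceComponents:
    """Build social-model components from a direct-social correlation."""
    sigma_uds = r_uds * math.sqrt(sigma2_ud * sigma2_us)
    return VarianceComponents(
        sigma2_ud, sigma2_us, sigma_uds, sigma2_gr, sigma2_cl, sigma2_cg,
        sigma2_e, model=SOCIAL,
    )
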