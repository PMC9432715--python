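"""Tissue-level survival, age-specific hazard, and pathway decomposition.

An organ carries ``K`` independent crypt niches and a single converted
crypt suffices to seed a cancer.  With per-crypt adenoma and carcinoma
probabilities ``Pa(t)``, ``Pc(t)`` and progression probability ``gamma``
(adenoma -> adenocarcinoma), the probability of remaining cancer-free is

    S(t) = (1 - Pc(t) - gamma * Pa(t)) ** K

and the age-specific incidence rate (hazard) is R(t) = -d/dt ln S(t),
evaluated here from the analytic absorption fluxes.  The hazard splits into
a tunneling part (carcinoma without a precursor adenoma) and a sequential
part (adenoma first), whose crossover age marks the switch from
de-novo-dominated early incidence to polyp-dominated incidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cryptcomp.niche import CryptAbsorptionCurves, NicheParams, ParameterDomainError

__all__ = [
    "TissueParams",
    "HazardCurves",
    "survival_and_hazard",
    "decompose_hazard",
    "lifetime_fractions",
]

PER_100K = 1e5


@dataclass(frozen=True)
class TissueParams:
    """Organ-scale parameters on top of a single niche.

    Parameters
    ----------
    K : int
        Number of crypts (niches) in the organ.
    gamma : float
        Probability that an adenoma progresses to adenocarcinoma.
    niche : NicheParams
        Parameters of the per-crypt competition process.
    """

    K: int
    gamma: float
    niche: NicheParams

    def __post_init__(self) -> None:
        if not self.K >= 1:
            raise ParameterDomainError(f"K must be >= 1, got {self.K!r}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ParameterDomainError(f"gamma must lie in [0, 1], got {self.gamma!r}")


@dataclass
class HazardCurves:
    """Survival and hazards on a time grid.

    ``R``, ``R_tunnel`` and ``R_seq`` are reported multiplied by ``scale``
    (default per 100,000 person-years); ``S`` is a probability.
    ``crossover_age`` is the age at which the tunneling and sequential
    hazards cross, or ``None`` if they do not cross inside the grid.
    """

    t: np.ndarray
    S: np.ndarray
    R: np.ndarray
    R_tunnel: np.ndarray
    R_seq: np.ndarray
    scale: float = PER_100K
    crossover_age: float | None = None

    def to_tsv(self, path) -> None:
        data = np.column_stack([self.t, self.S, self.R, self.R_tunnel, self.R_seq])
        np.savetxt(
            path,
            data,
            delimiter="\t",
            header=f"t_years\tS\tR_x{self.scale:g}\tR_tunnel_x{self.scale:g}"
            f"\tR_seq_x{self.scale:g}",
            comments="",
        )


def _combined_probability(
    curves: CryptAbsorptionCurves, tissue: TissueParams
) -> np.ndarray:
    q = curves.Pc + tissue.gamma * curves.Pa
    if np.any(q >= 1.0):
        raise ValueError(
            "Pc + gamma*Pa reaches 1 on the grid: certain cancer, outside the "
            "model regime"
        )
    return q


def survival_and_hazard(
    curves: CryptAbsorptionCurves, tissue: TissueParams, scale: float = PER_100K
) -> HazardCurves:
    """Lift per-crypt absorption curves to tissue survival and hazard.

    ``S`` is evaluated in log space as exp(K * log1p(-(Pc + gamma*Pa))) to
    remain accurate when the per-crypt probability is ~1e-8 and K ~ 1e7;
    ``R`` uses the analytic fluxes, never finite differences of ``S``.
    """
    q = _combined_probability(curves, tissue)
    S = np.exp(tissue.K * np.log1p(-q))
    flux = curves.dPc + tissue.gamma * curves.dPa
    R = tissue.K * flux / (1.0 - q)
    R_tunnel, R_seq, crossover = decompose_hazard(curves, tissue, scale=1.0)
    return HazardCurves(
        t=curves.t,
        S=S,
        R=R * scale,
        R_tunnel=R_tunnel * scale,
        R_seq=R_seq * scale,
        scale=scale,
        crossover_age=crossover,
    )


def decompose_hazard(
    curves: CryptAbsorptionCurves, tissue: TissueParams, scale: float = PER_100K
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Split the hazard into tunneling and sequential pathway contributions.

    R_tunnel = -d/dt ln(1 - Pc)^K        (carcinoma with no precursor)
    R_seq    = -d/dt ln(1 - gamma*Pa)^K  (progressed adenoma)

    Returns the two hazards (times ``scale``) and the crossover age where
    they are equal, located by linear interpolation at the sign change of
    their difference, or ``None`` when no crossing lies inside the grid.
    """
    _combined_probability(curves, tissue)  # domain check
    R_tunnel = tissue.K * curves.dPc / (1.0 - curves.Pc)
    R_seq = tissue.K * tissue.gamma * curves.dPa / (1.0 - tissue.gamma * curves.Pa)
    diff = R_tunnel - R_seq
    crossover: float | None = None
    # ignore grid points where both hazards are numerically negligible
    # (e.g. the exact zeros at t = 0), which otherwise fake a sign change
    mag = np.maximum(R_tunnel, R_seq)
    tol = 1e-9 * float(mag.max(initial=0.0))
    sign = np.where(mag > tol, np.sign(diff), 0.0)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if flips.size:
        k = flips[0]
        t0, t1 = curves.t[k], curves.t[k + 1]
        d0, d1 = diff[k], diff[k + 1]
        crossover = float(t0 + (t1 - t0) * d0 / (d0 - d1))
    elif np.any(diff == 0.0):
        crossover = float(curves.t[np.nonzero(diff == 0.0)[0][0]])
    return R_tunnel * scale, R_seq * scale, crossover


def lifetime_fractions(
    curves: CryptAbsorptionCurves, tissue: TissueParams, T: float = 85.0
) -> tuple[float, float]:
    """Lifetime pathway fractions at age ``T`` (default 85 years).

    Returns ``(sequential_fraction, benign_fraction)`` as fractions in
    [0, 1]:

    - sequential fraction: share of cancers that arose through a precursor
      adenoma, gamma*Pa(T) / (Pc(T) + gamma*Pa(T));
    - benign fraction: share of all tumors that are benign,
      Pa(T) / (Pc(T) + Pa(T)).
    """
    Pa_T, Pc_T = curves.at(T)
    Pa_T, Pc_T = float(Pa_T), float(Pc_T)
    if Pa_T + Pc_T <= 0.0:
        raise ZeroDivisionError(
            "both absorption probabilities are zero at T; fractions undefined"
        )
    denom = Pc_T + tissue.gamma * Pa_T
    seq = tissue.gamma * Pa_T / denom if denom > 0.0 else 0.0
    benign = Pa_T / (Pc_T + Pa_T)
    return seq, benign
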