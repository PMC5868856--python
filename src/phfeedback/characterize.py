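"""Species characterization and interaction-motif prediction.

The central claim this module operationalizes: knowing (i) a species' pH
niche — where on the pH axis it grows — and (ii) its pH drive — which way
it pushes the pH — is enough to anticipate the pairwise interaction motif.

Stage 1 fits the Gaussian-minus-death niche response to a fold-growth vs
initial-pH table (buffered assay): on a log scale the model is

    log(fold) = A * exp(-(p - p_pref)^2 / sigma^2) + B

with ``A`` the assay time scale and ``delta = -B/A`` the relative death
floor, fitted by nonlinear least squares on the model's proton scale
(display pH mapped linearly).  Stage 2 reads the drive sign and magnitude
from paired initial/final pH measurements.  Stage 3 classifies each
species as self-benefiting (drive moves the environment toward its own
optimum, evaluated from the assay's starting pH) or self-harming, and maps
the unordered pair of classes onto the interaction motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .model import ph_display_to_p, p_to_ph_display
from .outcomes import MotifLabel

__all__ = [
    "SpeciesProfile",
    "DegenerateFitError",
    "fit_ph_response",
    "estimate_ph_drive",
    "classify_self_effect",
    "predict_pair_motif",
    "profile_to_json",
]

#: Display-pH of the standard drive assay's starting medium.
ASSAY_START_PH = 7.0


class DegenerateFitError(ValueError):
    """The niche response is unidentifiable (flat table, too few levels...)."""


@dataclass
class SpeciesProfile:
    """Estimated pH niche and pH drive of one species.

    Niche estimates are on the model's proton scale (``p_pref``, ``sigma``,
    ``delta``); ``drive_sign`` is the direction of the species' *proton*
    drive (+1 raises proton concentration = lowers display pH), with
    ``drive_sign = 0`` when the measured pH shift is below the noise floor.
    """

    species: str = ""
    p_pref: float = float("nan")
    sigma: float = float("nan")
    delta: float = float("nan")
    amplitude: float = float("nan")
    residual: float = float("nan")
    drive_sign: int = 0
    drive_magnitude: float = float("nan")  # |median pH shift|, display units
    degenerate: bool = False
    provenance: str = ""

    @property
    def preferred_ph_display(self) -> float:
        return float(p_to_ph_display(self.p_pref))


def fit_ph_response(
    table: pd.DataFrame,
    b: float = 5.0,
    species: str | None = None,
    flat_tol: float = 0.05,
) -> SpeciesProfile:
    """Fit the Gaussian-minus-death niche to a fold-growth vs pH table.

    ``table`` needs columns ``pH_initial`` and ``fold_growth`` (replicates
    as repeated rows); fold growth must be positive (values < 1 indicate
    net death and identify the death floor).  The fit is scale-invariant
    for ``p_pref`` and ``sigma``: multiplying all folds by a constant only
    shifts the log-offset ``B``.  Raises :class:`DegenerateFitError` for a
    flat response (log-fold range below ``flat_tol``) or < 5 distinct pH
    levels; non-convergence returns a profile flagged degenerate.
    """
    if species is not None:
        table = table[table["species"] == species]
    name = species or (str(table["species"].iloc[0]) if "species" in table else "")
    ph = table["pH_initial"].to_numpy(float)
    fold = table["fold_growth"].to_numpy(float)
    if np.any(fold < 0):
        raise ValueError("fold growth must be >= 0")
    if len(np.unique(ph)) < 5:
        raise DegenerateFitError("need >= 5 distinct pH levels")
    keep = fold > 0  # zero folds carry no log-scale information
    ph, fold = ph[keep], fold[keep]
    p = ph_display_to_p(ph, b)
    y = np.log(fold)
    if y.max() - y.min() < flat_tol:
        raise DegenerateFitError("flat response: niche width unidentifiable")

    def model(pv, p_pref, sigma, A, B):
        return A * np.exp(-((pv - p_pref) ** 2) / sigma**2) + B

    p0 = [float(p[np.argmax(y)]), (p.max() - p.min()) / 2.0, float(y.max() - y.min()), float(y.min())]
    try:
        popt, _ = curve_fit(
            model,
            p,
            y,
            p0=p0,
            bounds=([-2.0 * b, 1e-3, 1e-6, -np.inf], [4.0 * b, 10.0 * b, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return SpeciesProfile(species=name, degenerate=True, provenance="fit_ph_response")
    p_pref, sigma, A, B = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((model(p, *popt) - y) ** 2)))
    delta = float(np.clip(-B / A, 1e-9, 1.0 - 1e-9))
    return SpeciesProfile(
        species=name,
        p_pref=p_pref,
        sigma=sigma,
        delta=delta,
        amplitude=A,
        residual=resid,
        provenance="fit_ph_response",
    )


def estimate_ph_drive(
    table: pd.DataFrame, noise_floor: float = 0.1
) -> tuple[int, float]:
    """Drive direction and magnitude from paired initial/final pH columns.

    Returns ``(sign, magnitude)`` where ``sign`` is the direction of the
    *proton* drive (+1 = acidifier: display pH fell) and ``magnitude`` the
    absolute median display-pH shift; shifts below ``noise_floor`` give
    sign 0.
    """
    if len(table) == 0:
        raise ValueError("empty input")
    shift = float(
        np.median(table["pH_final"].to_numpy(float) - table["pH_initial"].to_numpy(float))
    )
    if abs(shift) < noise_floor:
        return 0, abs(shift)
    return (-1 if shift > 0 else 1), abs(shift)


def characterize_species(
    growth_table: pd.DataFrame,
    endpoint_table: pd.DataFrame,
    b: float = 5.0,
    species: str | None = None,
) -> SpeciesProfile:
    """Convenience: niche fit plus drive estimate in one profile."""
    prof = fit_ph_response(growth_table, b=b, species=species)
    if species is not None:
        endpoint_table = endpoint_table[endpoint_table["species"] == species]
    prof.drive_sign, prof.drive_magnitude = estimate_ph_drive(endpoint_table)
    return prof


def classify_self_effect(
    profile: SpeciesProfile, assay_start_ph: float = ASSAY_START_PH, b: float = 5.0
) -> str:
    """``"benefit"`` if the species' drive moves ``p`` toward its own
    optimum from the assay starting pH, else ``"harm"``."""
    if profile.degenerate or profile.drive_sign == 0:
        raise DegenerateFitError(f"profile of '{profile.species}' is degenerate")
    p_start = float(ph_display_to_p(assay_start_ph, b))
    toward = np.sign(profile.p_pref - p_start)
    return "benefit" if toward == profile.drive_sign else "harm"


def predict_pair_motif(
    profile_a: SpeciesProfile,
    profile_b: SpeciesProfile,
    assay_start_ph: float = ASSAY_START_PH,
    b: float = 5.0,
) -> MotifLabel:
    """Map two species profiles onto the predicted interaction motif.

    The rule table (symmetric under swapping species):

    ========================  =========================  ==================
    self-effects              drive relation             predicted motif
    ========================  =========================  ==================
    benefit + benefit         opposing                   bistability
    benefit + benefit         same direction             coexistence
    harm + benefit            harm's drive toward the    successive_growth
                              partner's optimum
    harm + benefit            away from it               extended_suicide
    harm + harm               opposing                   stabilization
    harm + harm               same direction             ecological_suicide
    ========================  =========================  ==================
    """
    cls_a = classify_self_effect(profile_a, assay_start_ph, b)
    cls_b = classify_self_effect(profile_b, assay_start_ph, b)
    s_a, s_b = profile_a.drive_sign, profile_b.drive_sign
    opposing = s_a != s_b
    if cls_a == "benefit" and cls_b == "benefit":
        return MotifLabel.BISTABILITY if opposing else MotifLabel.COEXISTENCE
    if cls_a == "harm" and cls_b == "harm":
        return MotifLabel.STABILIZATION if opposing else MotifLabel.ECOLOGICAL_SUICIDE
    harm, partner = (
        (profile_a, profile_b) if cls_a == "harm" else (profile_b, profile_a)
    )
    p_start = float(ph_display_to_p(assay_start_ph, b))
    toward_partner = np.sign(partner.p_pref - p_start) == harm.drive_sign
    return MotifLabel.SUCCESSIVE_GROWTH if toward_partner else MotifLabel.EXTENDED_SUICIDE


def profile_to_json(profile: SpeciesProfile, path=None) -> str:
    payload = {
        k: (v if not isinstance(v, float) or np.isfinite(v) else None)
        for k, v in vars(profile).items()
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
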