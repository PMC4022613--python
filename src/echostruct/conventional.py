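"""Conventional echocardiographic and hemodynamic measures.

All lengths in cm, velocities in cm/s, pressures in mmHg, volumes in mL,
mass in g.  Relative wall thickness here is total wall thickness
(septum + posterior wall) over LV end-diastolic diameter — not the
2*PW/LVDD variant.
"""

from __future__ import annotations


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


def lvwt(ivs_cm: float, pw_cm: float) -> float:
    """Total LV wall thickness: septum width plus posterior wall width."""
    _require_positive(ivs_cm=ivs_cm, pw_cm=pw_cm)
    return ivs_cm + pw_cm


def rwt(lvwt_cm: float, lvdd_cm: float) -> float:
    """Relative wall thickness: total wall thickness over LVDD."""
    _require_positive(lvwt_cm=lvwt_cm, lvdd_cm=lvdd_cm)
    return lvwt_cm / lvdd_cm


def mean_arterial_pressure(sbp_mmHg: float, dbp_mmHg: float) -> float:
    """MAP = DBP + (SBP - DBP)/3; requires SBP > DBP > 0."""
    _require_positive(dbp_mmHg=dbp_mmHg)
    if sbp_mmHg <= dbp_mmHg:
        raise ValueError(f"sbp ({sbp_mmHg}) must exceed dbp ({dbp_mmHg})")
    return dbp_mmHg + (sbp_mmHg - dbp_mmHg) / 3.0


def _teichholz_volume(d_cm: float) -> float:
    return 7.0 / (2.4 + d_cm) * d_cm**3


def teichholz_volumes_ef(lvdd_cm: float, lvsd_cm: float) -> tuple:
    """(EDV mL, ESV mL, EF %) from linear diameters via the cube-law
    volume V = 7.0/(2.4 + D) * D^3."""
    _require_positive(lvdd_cm=lvdd_cm, lvsd_cm=lvsd_cm)
    if lvsd_cm >= lvdd_cm:
        raise ValueError(f"lvsd ({lvsd_cm}) must be smaller than lvdd ({lvdd_cm})")
    edv = _teichholz_volume(lvdd_cm)
    esv = _teichholz_volume(lvsd_cm)
    ef = 100.0 * (edv - esv) / edv
    return edv, esv, ef


def fractional_shortening(lvdd_cm: float, lvsd_cm: float) -> float:
    """FS = (LVDD - LVSD) / LVDD."""
    _require_positive(lvdd_cm=lvdd_cm, lvsd_cm=lvsd_cm)
    if lvsd_cm >= lvdd_cm:
        raise ValueError(f"lvsd ({lvsd_cm}) must be smaller than lvdd ({lvdd_cm})")
    return (lvdd_cm - lvsd_cm) / lvdd_cm


def lv_mass_devereux(ivs_cm: float, lvdd_cm: float, pw_cm: float) -> float:
    """ASE linear-method LV mass: 0.8*1.04*[(IVS+LVDD+PW)^3 - LVDD^3] + 0.6 g."""
    _require_positive(ivs_cm=ivs_cm, lvdd_cm=lvdd_cm, pw_cm=pw_cm)
    return 0.8 * 1.04 * ((ivs_cm + lvdd_cm + pw_cm) ** 3 - lvdd_cm**3) + 0.6


def diastolic_ratios(e_vel: float, a_vel: float, e_prime: float) -> tuple:
    """(E/A, E/e') from peak transmitral and annular velocities."""
    _require_positive(e_vel=e_vel, a_vel=a_vel, e_prime=e_prime)
    return e_vel / a_vel, e_vel / e_prime
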