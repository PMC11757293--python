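"""Hardcoded two-channel filter banks for the supported wavelet bases.

Coefficients are full-precision IEEE doubles for the standard orthogonal
(haar, db*, sym*) and biorthogonal spline (bior*) families, stored as
(dec_lo, dec_hi, rec_lo, rec_hi) analysis/synthesis quadruples.
"""

from __future__ import annotations

import numpy as np

_BANK: dict[str, tuple[tuple[float, ...], ...]] = {
    "haar": (
        (0.7071067811865476, 0.7071067811865476),
        (-0.7071067811865476, 0.7071067811865476),
        (0.7071067811865476, 0.7071067811865476),
        (0.7071067811865476, -0.7071067811865476),
    ),
    "db2": (
        (-0.12940952255126037, 0.2241438680420134, 0.8365163037378079, 0.48296291314453416),
        (-0.48296291314453416, 0.8365163037378079, -0.2241438680420134, -0.12940952255126037),
        (0.48296291314453416, 0.8365163037378079, 0.2241438680420134, -0.12940952255126037),
        (-0.12940952255126037, -0.2241438680420134, 0.8365163037378079, -0.48296291314453416),
    ),
    "db4": (
        (-0.010597401785069032, 0.0328830116668852, 0.030841381835560764, -0.18703481171909309, -0.027983769416859854, 0.6308807679298589, 0.7148465705529157, 0.2303778133088965),
        (-0.2303778133088965, 0.7148465705529157, -0.6308807679298589, -0.027983769416859854, 0.18703481171909309, 0.030841381835560764, -0.0328830116668852, -0.010597401785069032),
        (0.2303778133088965, 0.7148465705529157, 0.6308807679298589, -0.027983769416859854, -0.18703481171909309, 0.030841381835560764, 0.0328830116668852, -0.010597401785069032),
        (-0.010597401785069032, -0.0328830116668852, 0.030841381835560764, 0.18703481171909309, -0.027983769416859854, -0.6308807679298589, 0.7148465705529157, -0.2303778133088965),
    ),
    "sym4": (
        (-0.07576571478927333, -0.02963552764599851, 0.49761866763201545, 0.8037387518059161, 0.29785779560527736, -0.09921954357684722, -0.012603967262037833, 0.0322231006040427),
        (-0.0322231006040427, -0.012603967262037833, 0.09921954357684722, 0.29785779560527736, -0.8037387518059161, 0.49761866763201545, 0.02963552764599851, -0.07576571478927333),
        (0.0322231006040427, -0.012603967262037833, -0.09921954357684722, 0.29785779560527736, 0.8037387518059161, 0.49761866763201545, -0.02963552764599851, -0.07576571478927333),
        (-0.07576571478927333, 0.02963552764599851, 0.49761866763201545, -0.8037387518059161, 0.29785779560527736, 0.09921954357684722, -0.012603967262037833, -0.0322231006040427),
    ),
    "bior1.3": (
        (-0.08838834764831845, 0.08838834764831845, 0.7071067811865476, 0.7071067811865476, 0.08838834764831845, -0.08838834764831845),
        (-0.0, 0.0, -0.7071067811865476, 0.7071067811865476, -0.0, 0.0),
        (0.0, 0.0, 0.7071067811865476, 0.7071067811865476, 0.0, 0.0),
        (-0.08838834764831845, -0.08838834764831845, 0.7071067811865476, -0.7071067811865476, 0.08838834764831845, 0.08838834764831845),
    ),
    "bior3.5": (
        (-0.013810679320049757, 0.04143203796014927, 0.052480581416189075, -0.26792717880896527, -0.07181553246425873, 0.966747552403483, 0.966747552403483, -0.07181553246425873, -0.26792717880896527, 0.052480581416189075, 0.04143203796014927, -0.013810679320049757),
        (-0.0, 0.0, -0.0, 0.0, -0.1767766952966369, 0.5303300858899106, -0.5303300858899106, 0.1767766952966369, -0.0, 0.0, -0.0, 0.0),
        (0.0, 0.0, 0.0, 0.0, 0.1767766952966369, 0.5303300858899106, 0.5303300858899106, 0.1767766952966369, 0.0, 0.0, 0.0, 0.0),
        (-0.013810679320049757, -0.04143203796014927, 0.052480581416189075, 0.26792717880896527, -0.07181553246425873, -0.966747552403483, 0.966747552403483, 0.07181553246425873, -0.26792717880896527, -0.052480581416189075, 0.04143203796014927, 0.013810679320049757),
    ),
    "bior3.7": (
        (0.0030210861012608843, -0.009063258303782653, -0.01683176542131064, 0.074663985074019, 0.03133297870736289, -0.301159125922835, -0.02649924094534547, 0.9516421218971786, 0.9516421218971786, -0.02649924094534547, -0.301159125922835, 0.03133297870736289, 0.074663985074019, -0.01683176542131064, -0.009063258303782653, 0.0030210861012608843),
        (-0.0, 0.0, -0.0, 0.0, -0.0, 0.0, -0.1767766952966369, 0.5303300858899106, -0.5303300858899106, 0.1767766952966369, -0.0, 0.0, -0.0, 0.0, -0.0, 0.0),
        (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.1767766952966369, 0.5303300858899106, 0.5303300858899106, 0.1767766952966369, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        (0.0030210861012608843, 0.009063258303782653, -0.01683176542131064, -0.074663985074019, 0.03133297870736289, 0.301159125922835, -0.02649924094534547, -0.9516421218971786, 0.9516421218971786, 0.02649924094534547, -0.301159125922835, -0.03133297870736289, 0.074663985074019, 0.01683176542131064, -0.009063258303782653, -0.0030210861012608843),
    ),
    "bior3.9": (
        (-0.0006797443727836989, 0.002039233118351097, 0.005060319219611981, -0.020618912641105536, -0.014112787930175844, 0.09913478249423216, 0.012300136269419315, -0.32019196836077857, 0.0020500227115698858, 0.9421257006782068, 0.9421257006782068, 0.0020500227115698858, -0.32019196836077857, 0.012300136269419315, 0.09913478249423216, -0.014112787930175844, -0.020618912641105536, 0.005060319219611981, 0.002039233118351097, -0.0006797443727836989),
        (-0.0, 0.0, -0.0, 0.0, -0.0, 0.0, -0.0, 0.0, -0.1767766952966369, 0.5303300858899106, -0.5303300858899106, 0.1767766952966369, -0.0, 0.0, -0.0, 0.0, -0.0, 0.0, -0.0, 0.0),
        (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.1767766952966369, 0.5303300858899106, 0.5303300858899106, 0.1767766952966369, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        (-0.0006797443727836989, -0.002039233118351097, 0.005060319219611981, 0.020618912641105536, -0.014112787930175844, -0.09913478249423216, 0.012300136269419315, 0.32019196836077857, 0.0020500227115698858, -0.9421257006782068, 0.9421257006782068, -0.0020500227115698858, -0.32019196836077857, -0.012300136269419315, 0.09913478249423216, 0.014112787930175844, -0.020618912641105536, -0.005060319219611981, 0.002039233118351097, 0.0006797443727836989),
    ),
}


def available_wavelets() -> list[str]:
    """Names of the wavelet bases shipped with the package."""
    return sorted(_BANK)


def filter_bank(name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (dec_lo, dec_hi, rec_lo, rec_hi) as float64 arrays.

    Raises
    ------
    KeyError
        If `name` is not a shipped wavelet basis.
    """
    quad = _BANK[name]
    return tuple(np.asarray(f, dtype=np.float64) for f in quad)
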