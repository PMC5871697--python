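"""Boys function F_m(T) = \\int_0^1 u^{2m} exp(-T u^2) du.

Series evaluation at the highest required order with downward recursion
for the rest; large-T asymptotics where exp(-T) underflows the target
accuracy.  Absolute accuracy ~1e-14.
"""

from __future__ import annotations

import numpy as np

_T_SWITCH = 35.0


def boys(mmax: int, T: float) -> np.ndarray:
    """Return F_m(T) for m = 0..mmax."""
    out = np.empty(mmax + 1)
    if T < 1e-14:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1) - T / (2 * m + 3)
        return out
    if T > _T_SWITCH:
        # exp(-T) < 6e-16: asymptotic closed form, then downward recursion
        out[mmax] = _asymptotic(mmax, T)
        expT = 0.0
    else:
        out[mmax] = _series(mmax, T)
        expT = np.exp(-T)
    for m in range(mmax - 1, -1, -1):
        out[m] = (2.0 * T * out[m + 1] + expT) / (2 * m + 1)
    return out


def _series(m: int, T: float) -> float:
    # F_m(T) = exp(-T) * sum_k (2T)^k / (2m+1)(2m+3)...(2m+2k+1)
    term = 1.0 / (2 * m + 1)
    acc = term
    k = 1
    while True:
        term *= 2.0 * T / (2 * m + 2 * k + 1)
        acc += term
        if term < 1e-17 * acc:
            break
        k += 1
        if k > 500:  # pragma: no cover - safety valve
            break
    return float(np.exp(-T) * acc)


def _asymptotic(m: int, T: float) -> float:
    # F_m(T) ~ (2m-1)!! / 2^{m+1} * sqrt(pi / T^{2m+1})
    df = 1.0
    for n in range(2 * m - 1, 1, -2):
        df *= n
    return df / 2.0 ** (m + 1) * np.sqrt(np.pi / T ** (2 * m + 1))
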