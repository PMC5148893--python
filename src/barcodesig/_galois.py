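"""GF(256) arithmetic and Reed-Solomon codec for QR symbols.

Field: GF(2^8) with primitive polynomial x^8 + x^4 + x^3 + x^2 + 1
(0x11D), generator element 2, as prescribed for QR error correction.
Decoding corrects up to ``n_ec // 2`` byte errors per block using the
Berlekamp-Massey / Chien / Forney sequence.
"""

from __future__ import annotations

_EXP = [0] * 512
_LOG = [0] * 256
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= 0x11D
for _i in range(255, 512):
    _EXP[_i] = _EXP[_i - 255]


def gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("GF(256) division by zero")
    if a == 0:
        return 0
    return _EXP[(_LOG[a] - _LOG[b]) % 255]


def gf_pow(a: int, n: int) -> int:
    return _EXP[(_LOG[a] * n) % 255] if a else 0


def poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, pi in enumerate(p):
        if pi:
            for j, qj in enumerate(q):
                out[i + j] ^= gf_mul(pi, qj)
    return out


def poly_eval(p: list[int], x: int) -> int:
    """Evaluate polynomial (highest-order coefficient first) at x."""
    y = 0
    for coef in p:
        y = gf_mul(y, x) ^ coef
    return y


def rs_generator(n_ec: int) -> list[int]:
    """Generator polynomial prod_{i=0}^{n_ec-1} (x - alpha^i)."""
    g = [1]
    for i in range(n_ec):
        g = poly_mul(g, [1, _EXP[i]])
    return g


def rs_encode(data: list[int], n_ec: int) -> list[int]:
    """Return the ``n_ec`` Reed-Solomon parity bytes for ``data``."""
    gen = rs_generator(n_ec)
    rem = list(data) + [0] * n_ec
    for i in range(len(data)):
        coef = rem[i]
        if coef:
            for j in range(1, len(gen)):
                rem[i + j] ^= gf_mul(gen[j], coef)
    return rem[len(data):]


def rs_decode(codeword: list[int], n_ec: int) -> list[int]:
    """Correct up to n_ec//2 byte errors in data+parity; return data.

    Raises ValueError when the error pattern is uncorrectable.
    """
    msg = list(codeword)
    synd = [poly_eval(msg, _EXP[i]) for i in range(n_ec)]
    if not any(synd):
        return msg[: len(msg) - n_ec]

    # Berlekamp-Massey (Massey's formulation): find the error-locator
    # polynomial sigma, coefficients in ascending order, sigma[0] = 1.
    def _sub_scaled(p: list[int], coef: int, q: list[int]) -> list[int]:
        out = list(p) + [0] * max(0, len(q) - len(p))
        for i, qi in enumerate(q):
            out[i] ^= gf_mul(coef, qi)
        return out

    sigma = [1]
    prev_b = [1]
    L = 0
    m = 1
    b = 1
    for n in range(n_ec):
        delta = synd[n]
        for i in range(1, L + 1):
            if i < len(sigma):
                delta ^= gf_mul(sigma[i], synd[n - i])
        if delta == 0:
            m += 1
        elif 2 * L <= n:
            tmp = list(sigma)
            sigma = _sub_scaled(sigma, gf_div(delta, b), [0] * m + prev_b)
            L = n + 1 - L
            prev_b = tmp
            b = delta
            m = 1
        else:
            sigma = _sub_scaled(sigma, gf_div(delta, b), [0] * m + prev_b)
            m += 1
    while sigma and sigma[-1] == 0:
        sigma.pop()
    if L > n_ec // 2:
        raise ValueError("Reed-Solomon: too many errors to correct")

    # Chien search for error positions (roots of sigma).
    n = len(msg)
    positions = []
    for i in range(n):
        # x = alpha^{-i} corresponds to position n-1-i (highest order first)
        x_inv = _EXP[(255 - i) % 255]
        acc = 0
        for j, coef in enumerate(sigma):
            acc ^= gf_mul(coef, gf_pow(x_inv, j))
        if acc == 0:
            positions.append(n - 1 - i)
    if len(positions) != L:
        raise ValueError("Reed-Solomon: error locator does not factor; uncorrectable")

    # Forney algorithm for magnitudes.
    synd_poly = list(reversed(synd))  # highest order first
    omega_full = poly_mul(list(reversed(sigma)), synd_poly)
    omega = omega_full[len(omega_full) - n_ec:]  # mod x^n_ec
    sigma_deriv = []
    # derivative of sigma (ascending order): odd-power terms survive
    for j in range(1, len(sigma)):
        if j % 2 == 1:
            sigma_deriv.append((j - 1, sigma[j]))
    for pos in positions:
        x_inv = _EXP[(255 - (n - 1 - pos)) % 255]
        x = _EXP[(n - 1 - pos) % 255]
        num = poly_eval(omega, x_inv)
        den = 0
        for power, coef in sigma_deriv:
            den ^= gf_mul(coef, gf_pow(x_inv, power))
        if den == 0:
            raise ValueError("Reed-Solomon: Forney denominator zero; uncorrectable")
        magnitude = gf_mul(x, gf_div(num, den))
        msg[pos] ^= magnitude
    if any(poly_eval(msg, _EXP[i]) for i in range(n_ec)):
        raise ValueError("Reed-Solomon: correction failed verification")
    return msg[: len(msg) - n_ec]
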