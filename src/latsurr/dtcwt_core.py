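"""2-D Q-shift dual-tree complex wavelet transform (DT-CWT).

The DT-CWT decomposes an image into six complex-valued directional
subbands per scale (orientations roughly +-15, +-45, +-75 degrees) plus a
real approximation subband.  Unlike the critically-sampled real DWT, the
magnitude of the complex coefficients is nearly shift-invariant, which is
what makes subband energies a stable summary of the autocorrelation
structure of a lattice.

Implementation notes
--------------------
Level 1 uses the odd-length near-orthogonal pair applied without
decimation; the four polyphase corners of each highpass image are repacked
into two complex subbands (the two trees are realised implicitly as the
even/odd sample phases).  Levels >= 2 use the even-length Q-shift pair,
tree b being the time reverse of tree a.  All boundary handling is
half-sample symmetric extension (mirroring about the midpoint between the
edge sample and its ghost neighbour), so no abrupt transition is
introduced at the edges.

Every 1-D filtering step acts on an axis of fixed, known length, so it is
a fixed linear map.  These maps are materialised once per (operation,
filter, length) as small dense matrices and applied with ``matmul``, which
makes the transform fast and lets it broadcast over arbitrary leading
batch axes: an input of shape ``(..., rows, cols)`` is transformed as a
stack of images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._filters import DEFAULT_FILTER_BANK, FilterBank
from .grid_io import Lattice

__all__ = [
    "DTCWTPyramid",
    "FilterBank",
    "DEFAULT_FILTER_BANK",
    "dtcwt_forward",
    "dtcwt_inverse",
    "subband_energies",
    "max_level",
]

_SQRT_HALF = np.sqrt(0.5)


# ----------------------------------------------------------------------
# reference 1-D operations (index-based; used only to build matrices)
# ----------------------------------------------------------------------

def _reflect(x: np.ndarray, minx: float, maxx: float) -> np.ndarray:
    """Half-sample symmetric index reflection into [minx, maxx]."""
    rng = maxx - minx
    mod = np.fmod(x - minx, 2 * rng)
    mod = np.where(mod < 0, mod + 2 * rng, mod)
    out = np.where(mod >= rng, 2 * rng - mod, mod) + minx
    return np.rint(out).astype(int)


def _vconv(X: np.ndarray, h: np.ndarray) -> np.ndarray:
    """'valid' convolution along axis 0 (kernel flipped)."""
    W = sliding_window_view(X, len(h), axis=0)
    return W @ np.asarray(h)[::-1]


def _colfilter_ref(X: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Non-decimated column filtering with symmetric extension."""
    r = X.shape[0]
    m2 = len(h) // 2
    xe = _reflect(np.arange(-m2, r + m2), -0.5, r - 0.5)
    return _vconv(X[xe], h)


# Alignment of the two trees within the interleaved composite, in
# within-tree sample units.  Even composite slots carry the tree whose
# lowpass leads by a quarter sample; odd slots carry its time-reversed
# partner.  The lowpass outputs of the odd tree are placed half a
# sampling interval after the even tree's (D_LO), which is what lets the
# interleaved composite be consumed recursively by the next level, while
# the highpass outputs of the two trees are aligned to the same spatial
# positions (D_HI) so that even/odd pairs combine into near-analytic
# complex coefficients.  D_BASE centres the output grid so that the
# half-sample boundary reflection maps the composite onto itself, which
# keeps the per-axis analysis operator well conditioned at every size.
_D_BASE = 7
_D_LO = 1
_D_HI = -1


def _dt_decimate_ref(
    X: np.ndarray, h_even: np.ndarray, h_odd: np.ndarray, d_odd: int
) -> np.ndarray:
    """Dual-tree decimated column filtering of an interleaved composite.

    Rows of ``X`` alternate the two trees' samples.  Each tree filters its
    own subsample phase (with the composite extended by half-sample
    reflection *before* subsampling, so each tree's extension borrows the
    other tree's edge samples) and decimates by two within the tree:

        Y[2k]   = sum_n h_even[n] * x_ext[2*(2k + d - n)]
        Y[2k+1] = sum_n h_odd[n]  * x_ext[2*(2k + d + d_odd - n) + 1]

    with ``d = _D_BASE``.  Output has half the rows of ``X``.
    """
    r = X.shape[0]
    if r % 4:
        raise ValueError("rows must be a multiple of 4")
    m = len(h_even)
    n = np.arange(m)
    Y = np.zeros((r // 2,) + X.shape[1:])
    for k in range(r // 4):
        pe = 2 * (2 * k + _D_BASE - n)
        po = 2 * (2 * k + _D_BASE + d_odd - n) + 1
        Y[2 * k] = np.tensordot(h_even, X[_reflect(pe, -0.5, r - 0.5)], axes=1)
        Y[2 * k + 1] = np.tensordot(h_odd, X[_reflect(po, -0.5, r - 0.5)], axes=1)
    return Y


# ----------------------------------------------------------------------
# cached matrix operators
# ----------------------------------------------------------------------

_MATRIX_CACHE: dict[tuple, np.ndarray] = {}


def _pad_matrix(r: int) -> np.ndarray:
    """Edge-replicating pad of an axis to the next multiple of 4."""
    P = np.zeros((r + 2, r))
    P[0, 0] = 1.0
    P[1:-1] = np.eye(r)
    P[-1, -1] = 1.0
    return P


def _op_matrix(op: str, r: int, fb: FilterBank) -> np.ndarray:
    """Cached matrix operator for a 1-D analysis/synthesis step on length r.

    Analysis operators are built by applying the reference (index-based)
    filtering to an identity matrix.  Synthesis operators are the
    Moore-Penrose pseudo-inverses of the corresponding stacked analysis:
    for coefficients actually produced by the forward transform every
    left inverse reconstructs identically (perfect reconstruction), while
    for modified coefficient sets the pseudo-inverse gives the
    least-squares image, so that re-analysing a synthesised image is an
    orthogonal (non-expansive) projection — which keeps iterative
    coefficient-processing schemes stable.
    """
    key = (op, r, id(fb))
    M = _MATRIX_CACHE.get(key)
    if M is not None:
        return M
    eye = np.eye(r)
    if op == "lo1":
        M = _colfilter_ref(eye, fb.h0o)
    elif op == "hi1":
        M = _colfilter_ref(eye, fb.h1o)
    elif op in ("loq", "hiq", "loqp", "hiqp"):
        n = r + 2 if op.endswith("p") else r
        A = np.vstack([
            _dt_decimate_ref(np.eye(n), fb.h0a, fb.h0b, _D_LO),
            _dt_decimate_ref(np.eye(n), fb.h1a, fb.h1b, _D_HI),
        ])
        if op.endswith("p"):
            A = A @ _pad_matrix(r)
        # The interior rows of the stacked stage are exactly orthonormal
        # (the trees occupy disjoint sample phases and the Q-shift
        # prototype is orthonormal); the half-sample boundary reflection
        # mixes the phases, so the few boundary rows are not.  The polar
        # factor is the nearest matrix with orthonormal rows; it leaves
        # the interior untouched, makes the synthesis the plain
        # transpose, and renders coefficient re-projection non-expansive
        # (an iteration that modifies subbands then re-analyses cannot
        # blow up through the boundary modes).
        W, _, Vt = np.linalg.svd(A, full_matrices=False)
        U = W @ Vt  # polar factor: orthonormal columns, nearest to A
        h = A.shape[0] // 2
        if op in ("loq", "hiq"):
            _MATRIX_CACHE[("loq", r, id(fb))] = np.ascontiguousarray(U[:h])
            _MATRIX_CACHE[("hiq", r, id(fb))] = np.ascontiguousarray(U[h:])
            _MATRIX_CACHE[("gloq", h, id(fb))] = np.ascontiguousarray(U[:h].T)
            _MATRIX_CACHE[("ghiq", h, id(fb))] = np.ascontiguousarray(U[h:].T)
        else:
            _MATRIX_CACHE[("loqp", r, id(fb))] = np.ascontiguousarray(U[:h])
            _MATRIX_CACHE[("hiqp", r, id(fb))] = np.ascontiguousarray(U[h:])
            _MATRIX_CACHE[("gloqp", h, id(fb))] = np.ascontiguousarray(U[:h].T)
            _MATRIX_CACHE[("ghiqp", h, id(fb))] = np.ascontiguousarray(U[h:].T)
        return _MATRIX_CACHE[key]
    elif op in ("glo1", "ghi1"):
        A = np.vstack([_op_matrix("lo1", r, fb), _op_matrix("hi1", r, fb)])
        B = np.linalg.pinv(A)
        _MATRIX_CACHE[("glo1", r, id(fb))] = np.ascontiguousarray(B[:, :r])
        _MATRIX_CACHE[("ghi1", r, id(fb))] = np.ascontiguousarray(B[:, r:])
        return _MATRIX_CACHE[key]
    elif op in ("gloq", "ghiq"):
        _op_matrix(op[1:], 2 * r, fb)
        return _MATRIX_CACHE[key]
    elif op in ("gloqp", "ghiqp"):
        _op_matrix(op[1:], 2 * r - 2, fb)
        return _MATRIX_CACHE[key]
    else:  # pragma: no cover
        raise ValueError(op)
    _MATRIX_CACHE[key] = M
    return M


def _cols(op: str, X: np.ndarray, fb: FilterBank) -> np.ndarray:
    return _op_matrix(op, X.shape[-2], fb) @ X


def _rows(op: str, X: np.ndarray, fb: FilterBank) -> np.ndarray:
    return X @ _op_matrix(op, X.shape[-1], fb).T


# ----------------------------------------------------------------------
# quad <-> complex repacking
# ----------------------------------------------------------------------

def _q2c(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Repack 2x2 polyphase quads into two complex subband images."""
    p = (y[..., 0::2, 0::2] + 1j * y[..., 0::2, 1::2]) * _SQRT_HALF
    q = (y[..., 1::2, 1::2] - 1j * y[..., 1::2, 0::2]) * _SQRT_HALF
    return p - q, p + q


def _c2q(z1: np.ndarray, z2: np.ndarray) -> np.ndarray:
    P = (z1 + z2) * _SQRT_HALF
    Q = (z1 - z2) * _SQRT_HALF
    r2, c2 = z1.shape[-2:]
    x = np.zeros(z1.shape[:-2] + (2 * r2, 2 * c2))
    x[..., 0::2, 0::2] = P.real
    x[..., 0::2, 1::2] = P.imag
    x[..., 1::2, 0::2] = Q.imag
    x[..., 1::2, 1::2] = -Q.real
    return x


# ----------------------------------------------------------------------
# pyramid container
# ----------------------------------------------------------------------

@dataclass
class DTCWTPyramid:
    """Multiscale DT-CWT coefficient set.

    highpasses
        One complex array per level, shape ``(..., rk, ck, 6)``; the last
        axis indexes orientation (15, 45, 75, 105, 135, 165 degrees).
    lowpass
        Real coarsest approximation subband, shape ``(..., rL, cL)``.
    pad
        (rows, cols) of symmetric padding applied to reach even input
        dimensions; removed again on inversion.
    shape
        Spatial shape of the original (unpadded) input.
    """

    highpasses: list[np.ndarray]
    lowpass: np.ndarray
    pad: tuple[int, int]
    shape: tuple[int, int]
    level_pads: list[tuple[bool, bool]]

    @property
    def nlevels(self) -> int:
        return len(self.highpasses)


def max_level(shape: tuple[int, int]) -> int:
    """Deepest admissible decomposition, floor(log2(min dimension))."""
    return int(np.floor(np.log2(min(shape))))


def dtcwt_forward(
    x: Lattice | np.ndarray,
    nlevels: int | None = None,
    fb: FilterBank = DEFAULT_FILTER_BANK,
) -> DTCWTPyramid:
    """Forward transform of ``x`` (``(..., rows, cols)``; batch axes allowed).

    ``nlevels`` defaults to the maximum possible depth, log2 of the image
    size, so that autocorrelation at every scale is represented.
    """
    X = x.values if isinstance(x, Lattice) else np.asarray(x, dtype=float)
    shape = X.shape[-2:]
    lmax = max_level(shape)
    if nlevels is None:
        nlevels = lmax
    if nlevels < 1 or nlevels > lmax:
        raise ValueError(
            f"nlevels must be in [1, {lmax}] for shape {shape}, got {nlevels}"
        )
    pr, pc = X.shape[-2] % 2, X.shape[-1] % 2
    if pr:
        X = np.concatenate([X, X[..., -1:, :]], axis=-2)
    if pc:
        X = np.concatenate([X, X[..., :, -1:]], axis=-1)

    highpasses: list[np.ndarray] = []
    level_pads: list[tuple[bool, bool]] = [(False, False)]
    Lo = _cols("lo1", X, fb)
    Hi = _cols("hi1", X, fb)
    LoLo = _rows("lo1", Lo, fb)
    highpasses.append(_pack6(
        _q2c(_rows("lo1", Hi, fb)),   # horizontal pair -> bands 0, 5
        _q2c(_rows("hi1", Hi, fb)),   # diagonal pair   -> bands 1, 4
        _q2c(_rows("hi1", Lo, fb)),   # vertical pair   -> bands 2, 3
    ))
    for _ in range(1, nlevels):
        padr = bool(LoLo.shape[-2] % 4)
        padc = bool(LoLo.shape[-1] % 4)
        level_pads.append((padr, padc))
        lo_r, hi_r = ("loqp", "hiqp") if padr else ("loq", "hiq")
        lo_c, hi_c = ("loqp", "hiqp") if padc else ("loq", "hiq")
        Lo = _cols(lo_r, LoLo, fb)
        Hi = _cols(hi_r, LoLo, fb)
        LoLo = _rows(lo_c, Lo, fb)
        highpasses.append(_pack6(
            _q2c(_rows(lo_c, Hi, fb)),
            _q2c(_rows(hi_c, Hi, fb)),
            _q2c(_rows(hi_c, Lo, fb)),
        ))
    return DTCWTPyramid(highpasses, LoLo, (pr, pc), shape, level_pads)


def _pack6(lohi, hihi, hilo) -> np.ndarray:
    """Stack the three complex pairs into the 6-orientation axis.

    Order follows the conventional labelling from near-horizontal to
    near-vertical wavefront normals and back: approximately +15, +45,
    +75, -75, -45, -15 degrees.
    """
    return np.stack(
        [hilo[0], hihi[0], lohi[0], lohi[1], hihi[1], hilo[1]], axis=-1
    )


def dtcwt_inverse(
    p: DTCWTPyramid, fb: FilterBank = DEFAULT_FILTER_BANK
) -> Lattice | np.ndarray:
    """Inverse transform; returns a :class:`Lattice` for unbatched input."""
    Z = p.lowpass
    for lev in range(p.nlevels - 1, 0, -1):
        hp = p.highpasses[lev]
        if hp.shape[-3:-1] != tuple(s // 2 for s in Z.shape[-2:]):
            raise ValueError("pyramid shapes are inconsistent")
        padr, padc = p.level_pads[lev]
        glo_r, ghi_r = ("gloqp", "ghiqp") if padr else ("gloq", "ghiq")
        glo_c, ghi_c = ("gloqp", "ghiqp") if padc else ("gloq", "ghiq")
        hl = _c2q(hp[..., 0], hp[..., 5])
        hh = _c2q(hp[..., 1], hp[..., 4])
        lh = _c2q(hp[..., 2], hp[..., 3])
        y1 = _cols(glo_r, Z, fb) + _cols(ghi_r, lh, fb)
        y2 = _cols(glo_r, hl, fb) + _cols(ghi_r, hh, fb)
        Z = _rows(glo_c, y1, fb) + _rows(ghi_c, y2, fb)
    hp = p.highpasses[0]
    if hp.shape[-3:-1] != tuple(s // 2 for s in Z.shape[-2:]):
        raise ValueError("pyramid shapes are inconsistent")
    hl = _c2q(hp[..., 0], hp[..., 5])
    hh = _c2q(hp[..., 1], hp[..., 4])
    lh = _c2q(hp[..., 2], hp[..., 3])
    y1 = _cols("glo1", Z, fb) + _cols("ghi1", lh, fb)
    y2 = _cols("glo1", hl, fb) + _cols("ghi1", hh, fb)
    Z = _rows("glo1", y1, fb) + _rows("ghi1", y2, fb)
    pr, pc = p.pad
    if pr:
        Z = Z[..., :-1, :]
    if pc:
        Z = Z[..., :, :-1]
    if Z.ndim == 2:
        return Lattice(Z)
    return Z


def subband_energies(p: DTCWTPyramid, isotropic: bool = False) -> np.ndarray:
    """Summed squared magnitudes of the detail coefficients.

    Returns shape ``(..., L, 6)`` — one energy per scale and orientation —
    or ``(..., L)`` with orientations pooled when ``isotropic`` is true.
    """
    e = np.stack(
        [np.sum(np.abs(h) ** 2, axis=(-3, -2)) for h in p.highpasses], axis=-2
    )
    return e.sum(axis=-1) if isotropic else e
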