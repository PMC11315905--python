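"""im2col-based 2-D convolution and pooling primitives (stride-1 conv).

Arrays are channels-last: batches ``(batch, h, w, c)``, kernels
``(kh, kw, cin, cout)``.  Convolution is implemented as a dense matrix
product on extracted patches so the spiking forward/backward passes can
share one code path between dense and convolutional layers.
"""

from __future__ import annotations

import numpy as np


def conv_out_shape(in_shape, kernel_shape, padding: str):
    h, w, _ = in_shape
    kh, kw, _, cout = kernel_shape
    if padding == "same":
        return (h, w, cout)
    if padding == "valid":
        return (h - kh + 1, w - kw + 1, cout)
    raise ValueError(f"unknown padding {padding!r}")


def _pad_amount(kh, kw, padding):
    if padding == "same":
        return (kh - 1) // 2, kh - 1 - (kh - 1) // 2, (kw - 1) // 2, kw - 1 - (kw - 1) // 2
    return 0, 0, 0, 0


def im2col(x: np.ndarray, kh: int, kw: int, padding: str, fill: float = 0.0):
    """Extract ``(batch, oh, ow, kh*kw*cin)`` patches (stride 1).

    ``fill`` is the value used for padded positions; spike-time frames pad
    with a value that decodes to activation zero.
    """
    b, h, w, c = x.shape
    pt, pb, pl, pr = _pad_amount(kh, kw, padding)
    if pt or pb or pl or pr:
        x = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)),
                   constant_values=fill)
    oh = x.shape[1] - kh + 1
    ow = x.shape[2] - kw + 1
    s0, s1, s2, s3 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(b, oh, ow, kh, kw, c), strides=(s0, s1, s2, s1, s2, s3),
        writeable=False,
    )
    return patches.reshape(b, oh, ow, kh * kw * c)


def col2im(cols: np.ndarray, in_shape, kh: int, kw: int, padding: str):
    """Adjoint of :func:`im2col`: scatter-add patch values back."""
    b = cols.shape[0]
    h, w, c = in_shape
    pt, pb, pl, pr = _pad_amount(kh, kw, padding)
    hp, wp = h + pt + pb, w + pl + pr
    out = np.zeros((b, hp, wp, c), dtype=cols.dtype)
    oh, ow = cols.shape[1], cols.shape[2]
    cols = cols.reshape(b, oh, ow, kh, kw, c)
    for i in range(kh):
        for j in range(kw):
            out[:, i:i + oh, j:j + ow, :] += cols[:, :, :, i, j, :]
    return out[:, pt:pt + h, pl:pl + w, :]


def conv_forward(x: np.ndarray, kernel: np.ndarray, padding: str):
    """Stride-1 convolution; returns ``(out, patches)``."""
    kh, kw, cin, cout = kernel.shape
    patches = im2col(x, kh, kw, padding)
    out = patches @ kernel.reshape(kh * kw * cin, cout)
    return out, patches


def conv_backward(g_out: np.ndarray, patches: np.ndarray, kernel: np.ndarray,
                  in_shape, padding: str):
    """Gradients of a stride-1 convolution.

    Returns ``(g_kernel, g_in)`` for output gradient ``g_out`` of shape
    ``(batch, oh, ow, cout)``.
    """
    kh, kw, cin, cout = kernel.shape
    gk = np.tensordot(patches, g_out, axes=([0, 1, 2], [0, 1, 2]))
    g_cols = g_out @ kernel.reshape(kh * kw * cin, cout).T
    g_in = col2im(g_cols, in_shape, kh, kw, padding)
    return gk.reshape(kernel.shape), g_in


def pool_view(x: np.ndarray, pool: int, stride: int):
    """Non-overlapping-style pooling windows ``(batch, oh, ow, p*p, c)``.

    Requires ``stride == pool`` (the only configuration used here) and
    trims trailing rows/columns that do not fill a window.
    """
    if stride != pool:
        raise ValueError("pooling requires stride == pool")
    b, h, w, c = x.shape
    oh, ow = h // pool, w // pool
    x = x[:, :oh * pool, :ow * pool, :]
    return x.reshape(b, oh, pool, ow, pool, c).transpose(0, 1, 3, 2, 4, 5) \
            .reshape(b, oh, ow, pool * pool, c)


def pool_scatter(g_out: np.ndarray, argsel: np.ndarray, in_shape,
                 pool: int, stride: int):
    """Route pooled gradients back to the selected window members."""
    b = g_out.shape[0]
    h, w, c = in_shape
    oh, ow = h // pool, w // pool
    g_win = np.zeros((b, oh, ow, pool * pool, c), dtype=g_out.dtype)
    np.put_along_axis(g_win, argsel[:, :, :, None, :], g_out[:, :, :, None, :], axis=3)
    g_in = np.zeros((b, h, w, c), dtype=g_out.dtype)
    g_trim = g_win.reshape(b, oh, ow, pool, pool, c).transpose(0, 1, 3, 2, 4, 5) \
                  .reshape(b, oh * pool, ow * pool, c)
    g_in[:, :oh * pool, :ow * pool, :] = g_trim
    return g_in
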