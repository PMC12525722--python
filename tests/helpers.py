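"""Shared numeric test utilities."""

import numpy as np

from ddilink.autodiff import Tensor


def finite_diff_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


def check_gradient(build, x0, tol=1e-6):
    """build(Tensor) -> scalar Tensor; compares analytic vs numeric grads."""
    t = Tensor(x0, requires_grad=True)
    out = build(t)
    out.backward()
    num = finite_diff_grad(lambda x: float(build(Tensor(x, True)).data), x0)
    np.testing.assert_allclose(t.grad, num, rtol=tol, atol=tol)
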