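"""Gaussian-process classification with a linear kernel, Laplace posterior.

Binary classification uses the logistic likelihood with the standard
Newton/IRLS mode finding in the stable parameterization (no explicit kernel
inverse); multiclass uses the softmax likelihood with a damped Newton solver
on the stacked latent vector.  The kernel is

    k(x, x') = sigma0^2 + x . x'

i.e. a linear kernel plus a constant bias component; the bias lets the
latent mean absorb class base rates (with pure dot-product kernels an
all-zero feature matrix would force p = 0.5 regardless of the priors).

Because the kernel is linear, the posterior-mode predictor is itself linear:
at the mode f_hat = K alpha with alpha = t - pi_hat, so the voxel-space
weights are w = X^T alpha and the bias w0 = sigma0^2 * sum(alpha).
Predictions plug the latent mean into the link (MAP plug-in); no predictive
variance correction is applied, keeping the classifier deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, softmax

__all__ = ["LaplaceGPC", "GPCNotConverged"]

_JITTER = 1e-10


class GPCNotConverged(RuntimeError):
    """Newton mode finding failed to converge within the iteration budget."""


@dataclass
class LaplaceGPC:
    """Laplace-approximate GP classifier with linear(+bias) kernel.

    Parameters
    ----------
    sigma0_sq : float
        Variance of the constant kernel component (bias prior).
    max_iter : int
        Newton iteration budget for the posterior mode.
    tol : float
        Convergence tolerance on the change of the penalized log likelihood.
    """

    sigma0_sq: float = 10.0
    max_iter: int = 100
    tol: float = 1e-9

    # set by fit()
    classes_: np.ndarray | None = None
    weights_: np.ndarray | None = None  # (V,) binary, (C, V) multiclass
    bias_: np.ndarray | float | None = None
    multiclass_: bool = False

    def _kernel(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        return self.sigma0_sq + x @ z.T

    def fit(self, x: np.ndarray, y: np.ndarray) -> "LaplaceGPC":
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        k = self._kernel(x, x)
        if n_classes == 2:
            t = (y == self.classes_[1]).astype(np.float64)
            alpha = self._fit_binary(k, t)
            self.weights_ = x.T @ alpha
            self.bias_ = float(self.sigma0_sq * alpha.sum())
            self.multiclass_ = False
        else:
            t = (y[None, :] == self.classes_[:, None]).astype(np.float64)
            alpha = self._fit_multiclass(k, t)  # (C, n)
            self.weights_ = alpha @ x  # (C, V)
            self.bias_ = self.sigma0_sq * alpha.sum(axis=1)
            self.multiclass_ = True
        return self

    def _fit_binary(self, k: np.ndarray, t: np.ndarray) -> np.ndarray:
        n = len(t)
        f = np.zeros(n)
        obj_prev = -np.inf
        for iteration in range(self.max_iter):
            pi = expit(f)
            w = pi * (1.0 - pi)
            sw = np.sqrt(w)
            b_mat = np.eye(n) + sw[:, None] * k * sw[None, :]
            chol = cho_factor(b_mat, lower=True)
            grad = t - pi
            b = w * f + grad
            a = b - sw * cho_solve(chol, sw * (k @ b))
            f = k @ a
            # penalized log-likelihood at the new mode iterate
            pi = expit(f)
            loglik = float(np.sum(t * np.log(pi + _JITTER) + (1 - t) * np.log(1 - pi + _JITTER)))
            obj = -0.5 * float(a @ f) + loglik
            if abs(obj - obj_prev) < self.tol:
                return t - expit(f)
            obj_prev = obj
        raise GPCNotConverged(
            f"binary Laplace Newton did not converge in {self.max_iter} iterations "
            f"(last objective {obj_prev:.6g})"
        )

    def _fit_multiclass(self, k: np.ndarray, t: np.ndarray) -> np.ndarray:
        # Newton mode finding in the inverse-free parameterization: each
        # step works with chol(I + D_c^{1/2} K D_c^{1/2}) per class, so a
        # rank-deficient kernel (e.g. constant features) stays stable.
        c, n = t.shape
        f = np.zeros((c, n))
        eye = np.eye(n)
        obj_prev = -np.inf
        for iteration in range(self.max_iter):
            pi = softmax(f, axis=0)  # (C, n)
            # b = W f + (t - pi) with W = D - Pi Pi^T
            pif = np.sum(pi * f, axis=0)
            b = pi * f - pi * pif[None, :] + t - pi
            e_blocks = np.empty((c, n, n))
            for ci in range(c):
                sd = np.sqrt(pi[ci])
                chol = cho_factor(eye + sd[:, None] * k * sd[None, :], lower=True)
                e_blocks[ci] = sd[:, None] * cho_solve(chol, np.diag(sd))
            m_chol = cho_factor(e_blocks.sum(axis=0), lower=True)
            cvec = np.stack([e_blocks[ci] @ (k @ b[ci]) for ci in range(c)])
            rc = cvec.sum(axis=0)
            corr = cho_solve(m_chol, rc)
            a = b - cvec + np.stack([e_blocks[ci] @ corr for ci in range(c)])
            f = np.stack([k @ a[ci] for ci in range(c)])
            obj = float(
                -0.5 * np.sum(a * f)
                + np.sum(t * f)
                - np.sum(np.log(np.sum(np.exp(f - f.max(axis=0)), axis=0)) + f.max(axis=0))
            )
            if abs(obj - obj_prev) < self.tol:
                return t - softmax(f, axis=0)
            obj_prev = obj
        raise GPCNotConverged(
            f"multiclass Laplace Newton did not converge in {self.max_iter} "
            f"iterations (last objective {obj_prev:.6g})"
        )

    def latent(self, x: np.ndarray) -> np.ndarray:
        """Posterior-mean latent value(s) at x: f = w0 + w.x."""
        x = np.asarray(x, dtype=np.float64)
        if self.multiclass_:
            return self.bias_[:, None] + self.weights_ @ x.T  # (C, m)
        return self.bias_ + x @ self.weights_

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        f = self.latent(x)
        if self.multiclass_:
            return softmax(f, axis=0).T  # (m, C)
        p1 = expit(f)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, x: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(x)
        return self.classes_[np.argmax(proba, axis=1)]
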