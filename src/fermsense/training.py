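"""Training engines for the soft-sensor networks.

Three full-batch engines minimize the normalized-space MSE:

* ``scg`` — Møller's scaled conjugate gradient with analytic gradients;
* ``lm`` — Levenberg–Marquardt on the residual vector with a per-sample
  Jacobian from backpropagation; the damping factor shrinks on accepted
  steps and grows on rejected ones, so accepted steps never increase the
  training error;
* ``br`` — Bayesian regularization: a Levenberg–Marquardt inner loop on
  beta·ED + alpha·EW with MacKay evidence re-estimation of (alpha, beta);
  the validation subset is not used for stopping.

SCG and LM stop early at the validation-error minimum (patience in epochs)
and return the weights of that epoch; every engine also stops once the
normalized-space training error (RMSE) reaches the goal.  Training is restarted from several seeded
initializations and the best restart is returned.
"""

from __future__ import annotations

import numpy as np

from .ann import (
    AnnModel,
    AnnSpec,
    MinMaxNormalizer,
    evaluate,
    forward_normalized,
    loss_and_grad,
    mse,
    n_params,
    pack,
    residuals_and_jacobian,
    split_dataset,
    unpack,
)

__all__ = ["init_weights", "train_ann", "train_scg", "train_lm", "train_bayes_reg"]


def init_weights(n_in: int, n_hid: int, rng: np.random.Generator) -> np.ndarray:
    """Nguyen–Widrow-style initialization: uniform hidden weights rescaled so
    each hidden unit's input weight vector has magnitude 0.7·H^(1/I)."""
    w1 = rng.uniform(-0.5, 0.5, size=(n_hid, n_in))
    norms = np.linalg.norm(w1, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    scale = 0.7 * n_hid ** (1.0 / n_in)
    w1 = scale * w1 / norms
    b1 = rng.uniform(-scale, scale, size=n_hid)
    w2 = rng.uniform(-0.5, 0.5, size=n_hid)
    b2 = rng.uniform(-0.5, 0.5)
    return pack(w1, b1, w2, b2)


class _Tracker:
    """Per-epoch history with early stopping at the validation minimum."""

    def __init__(self, xv, yv, xt, yt, n_hid, patience, use_val):
        self.xv, self.yv, self.xt, self.yt = xv, yv, xt, yt
        self.n_hid = n_hid
        self.patience = patience
        self.use_val = use_val and xv is not None and len(xv)
        self.train_mse: list[float] = []
        self.val_mse: list[float] = []
        self.test_mse: list[float] = []
        self.best_theta = None
        self.best_val = np.inf
        self.best_epoch = -1
        self.stall = 0

    def record(self, theta, train) -> bool:
        """Log one epoch; True means stop (validation stalled)."""
        self.train_mse.append(train)
        v = mse(theta, self.xv, self.yv, self.n_hid) if self.use_val else np.nan
        self.val_mse.append(v)
        if self.xt is not None and len(self.xt):
            self.test_mse.append(mse(theta, self.xt, self.yt, self.n_hid))
        crit = v if self.use_val else train
        if crit < self.best_val - 1e-15:
            self.best_val = crit
            self.best_theta = theta.copy()
            self.best_epoch = len(self.train_mse) - 1
            self.stall = 0
        else:
            self.stall += 1
        return self.use_val and self.stall > self.patience

    def history(self, stop_reason) -> dict:
        return {
            "train_mse": self.train_mse,
            "val_mse": self.val_mse,
            "test_mse": self.test_mse,
            "stopping_epoch": self.best_epoch,
            "stop_reason": stop_reason,
        }


def train_scg(
    theta0, xn, yn, *, n_hid, goal=1e-3, max_epochs=1000, patience=6,
    xn_val=None, yn_val=None, xn_test=None, yn_test=None,
):
    """Scaled conjugate gradient (Møller 1993) on the full-batch MSE."""
    theta = theta0.copy()
    n = theta.size
    sigma0, lam, lam_bar = 5e-5, 5e-7, 0.0
    f, grad = loss_and_grad(theta, xn, yn, n_hid)
    r = -grad
    p = r.copy()
    success = True
    track = _Tracker(xn_val, yn_val, xn_test, yn_test, n_hid, patience, True)
    reason = "max_epochs"
    delta = 1.0
    for k in range(max_epochs):
        pnorm2 = float(p @ p)
        if pnorm2 < 1e-300:
            reason = "gradient_vanished"
            break
        if success:
            sigma = sigma0 / np.sqrt(pnorm2)
            _, grad_s = loss_and_grad(theta + sigma * p, xn, yn, n_hid)
            s = (grad_s - grad) / sigma
            delta = float(p @ s)
        delta += (lam - lam_bar) * pnorm2
        if delta <= 0:  # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta / pnorm2)
            delta = -delta + lam * pnorm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new = mse(theta + alpha * p, xn, yn, n_hid)
        big_delta = 2.0 * delta * (f - f_new) / (mu * mu)
        if big_delta >= 0:
            theta = theta + alpha * p
            f, grad = loss_and_grad(theta, xn, yn, n_hid)
            r_new = -grad
            lam_bar = 0.0
            success = True
            if (k + 1) % n == 0:
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if big_delta >= 0.75:
                lam = max(lam * 0.25, 1e-20)
        else:
            lam_bar = lam
            success = False
        if big_delta < 0.25:
            lam += delta * (1.0 - big_delta) / pnorm2
        if not np.isfinite(f):
            raise FloatingPointError("SCG diverged to a non-finite loss")
        if track.record(theta, f):
            reason = "early_stopping"
            break
        if f <= goal * goal:
            reason = "goal"
            break
        if float(r @ r) < 1e-18:
            reason = "gradient_vanished"
            break
    best = track.best_theta if track.best_theta is not None else theta
    return best, track.history(reason)


def _lm_core(
    theta0, xn, yn, *, n_hid, goal, max_epochs, patience,
    xn_val, yn_val, xn_test, yn_test,
    alpha=0.0, beta=1.0, update_hyper=False, use_val_stopping=True,
):
    """Levenberg–Marquardt loop; with alpha > 0 / update_hyper it becomes the
    Bayesian-regularization engine (objective beta·ED + alpha·EW,
    ED = ½Σr², EW = ½‖w‖²)."""
    theta = theta0.copy()
    p = theta.size
    n_res = len(yn)
    lam = 1e-3
    track = _Tracker(
        xn_val, yn_val, xn_test, yn_test, n_hid, patience, use_val_stopping
    )
    reason = "max_epochs"
    gamma = float(p)
    eye = np.eye(p)
    for _ in range(max_epochs):
        r, j = residuals_and_jacobian(theta, xn, yn, n_hid)
        sse = float(r @ r)
        jtj = j.T @ j
        g = beta * (j.T @ r) + alpha * theta
        obj = beta * 0.5 * sse + alpha * 0.5 * float(theta @ theta)
        accepted = False
        h = beta * jtj + alpha * eye
        # Marquardt scaling: damp along diag(H) so poorly scaled directions
        # are regularized proportionally
        damp = np.diag(np.maximum(np.diag(h), 1e-12))
        for _try in range(25):
            try:
                step = np.linalg.solve(h + lam * damp, -g)
            except np.linalg.LinAlgError:
                lam = max(lam, 1e-12) * 10.0
                continue
            cand = theta + step
            r_c, _, _ = forward_normalized(cand, xn, n_hid)
            sse_c = float(np.sum((r_c - yn) ** 2))
            obj_c = beta * 0.5 * sse_c + alpha * 0.5 * float(cand @ cand)
            if np.isfinite(obj_c) and obj_c < obj:
                theta = cand
                sse = sse_c
                lam = max(lam * 0.1, 1e-14)
                accepted = True
                break
            lam *= 10.0
            if lam > 1e12:
                break
        train_mse = sse / n_res
        if update_hyper:
            # MacKay evidence update with the Gauss-Newton Hessian
            r, j = residuals_and_jacobian(theta, xn, yn, n_hid)
            sse = float(r @ r)
            jtj = j.T @ j
            h = beta * jtj + alpha * eye
            try:
                gamma = p - alpha * float(np.trace(np.linalg.inv(h)))
            except np.linalg.LinAlgError:
                gamma = float(p)
            gamma = min(max(gamma, 1e-9), float(p) - 1e-9)
            ew = 0.5 * float(theta @ theta)
            ed = 0.5 * sse
            alpha = gamma / max(2.0 * ew, 1e-12)
            beta = max(n_res - gamma, 1e-9) / max(2.0 * ed, 1e-12)
        if track.record(theta, train_mse):
            reason = "early_stopping"
            break
        if train_mse <= goal * goal:
            reason = "goal"
            break
        if not accepted:
            reason = "damping_exhausted"
            break
    best = (
        track.best_theta
        if (use_val_stopping and track.best_theta is not None)
        else theta
    )
    hist = track.history(reason)
    if update_hyper:
        hist.update(
            alpha=float(alpha), beta=float(beta), gamma=float(gamma), n_params=p
        )
    return best, hist


def train_lm(
    theta0, xn, yn, *, n_hid, goal=1e-3, max_epochs=300, patience=6,
    xn_val=None, yn_val=None, xn_test=None, yn_test=None,
):
    """Levenberg–Marquardt with validation early stopping."""
    return _lm_core(
        theta0, xn, yn, n_hid=n_hid, goal=goal, max_epochs=max_epochs,
        patience=patience, xn_val=xn_val, yn_val=yn_val,
        xn_test=xn_test, yn_test=yn_test,
    )


def train_bayes_reg(
    theta0, xn, yn, *, n_hid, goal=1e-3, max_epochs=300, patience=6,
    xn_val=None, yn_val=None, xn_test=None, yn_test=None,
    alpha_init=1e-4, beta_init=1.0, update_hyper=True,
):
    """Bayesian regularization; with alpha_init=0 and update_hyper=False this
    reduces exactly to Levenberg–Marquardt without early stopping."""
    return _lm_core(
        theta0, xn, yn, n_hid=n_hid, goal=goal, max_epochs=max_epochs,
        patience=patience, xn_val=xn_val, yn_val=yn_val,
        xn_test=xn_test, yn_test=yn_test,
        alpha=alpha_init, beta=beta_init, update_hyper=update_hyper,
        use_val_stopping=False,
    )


_ENGINE_FN = {"scg": train_scg, "lm": train_lm, "br": train_bayes_reg}


def train_ann(spec: AnnSpec, x: np.ndarray, y: np.ndarray, feature_names=None,
              output_name=None) -> AnnModel:
    """Split, normalize, train with restarts and return the best model.

    Normalization constants come from the training subset only.  The best
    restart is chosen by validation MSE (training MSE for the
    Bayesian-regularization engine, which does not use the validation
    subset).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise ValueError("x and y row counts differ")
    if x.shape[1] != spec.n_inputs:
        raise ValueError(f"spec expects {spec.n_inputs} inputs, data has {x.shape[1]}")
    i_tr, i_val, i_te = split_dataset(y.size, spec.split, spec.seed)
    x_norm = MinMaxNormalizer.fit(x[i_tr], feature_names)
    y_norm = MinMaxNormalizer.fit(y[i_tr][:, None])
    xn = x_norm.transform(x)
    yn = y_norm.transform(y[:, None]).ravel()

    fn = _ENGINE_FN[spec.engine]
    rng = np.random.default_rng(spec.seed)
    best = None
    failures = []
    for rep in range(spec.restarts):
        theta0 = init_weights(spec.n_inputs, spec.n_hidden, rng)
        try:
            theta, hist = fn(
                theta0, xn[i_tr], yn[i_tr],
                n_hid=spec.n_hidden, goal=spec.goal, max_epochs=spec.epochs,
                patience=spec.patience,
                xn_val=xn[i_val], yn_val=yn[i_val],
                xn_test=xn[i_te], yn_test=yn[i_te],
            )
        except FloatingPointError as exc:
            failures.append(str(exc))
            continue
        if spec.engine == "br":
            crit = mse(theta, xn[i_tr], yn[i_tr], spec.n_hidden)
        else:
            crit = mse(theta, xn[i_val], yn[i_val], spec.n_hidden) if len(i_val) else (
                mse(theta, xn[i_tr], yn[i_tr], spec.n_hidden)
            )
        if not np.isfinite(crit):
            failures.append("non-finite selection criterion")
            continue
        if best is None or crit < best[0]:
            best = (crit, theta, hist, rep)
    if best is None:
        raise RuntimeError(
            f"every restart failed for engine {spec.engine}: {failures}"
        )
    _, theta, hist, rep = best
    model = AnnModel(
        theta=theta,
        n_inputs=spec.n_inputs,
        n_hidden=spec.n_hidden,
        engine=spec.engine,
        x_norm=x_norm,
        y_norm=y_norm,
        feature_names=tuple(feature_names) if feature_names else None,
        output_name=output_name,
        history={**hist, "restart": rep, "n_restarts": spec.restarts},
        seed=spec.seed,
    )
    for label, idx in (("train", i_tr), ("val", i_val), ("test", i_te)):
        if len(idx):
            rm, r2 = evaluate(y[idx], model.forward(x[idx]))
            model.metrics[label] = {"rmse": rm, "r2": r2}
    rm, r2 = evaluate(y, model.forward(x))
    model.metrics["total"] = {"rmse": rm, "r2": r2}
    return model
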