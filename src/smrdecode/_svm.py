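"""Exact linear-SVM dual solver with warm starts.

The adaptive classifier retrains a C-SVM every 400 ms on rolling buffers
that change by one frame at a time, so the solver must deliver the *exact*
batch solution cheaply from a warm start.  This module implements a primal
active-set method on the SVM dual QP

    min  1/2 a' Q a - e' a   s.t.  y' a = 0,  0 <= a <= C,   Q = (y∘X)(y∘X)'

exploiting that with a linear kernel the free support set is small (at most
about n_features + 1 points generically): each outer iteration solves the
equality-constrained KKT system on the free set directly and either hits a
bound or verifies global optimality.  Warm-started from the previous
buffer's multipliers the method typically converges in 1-3 outer
iterations, and the result satisfies the KKT conditions to near machine
precision — retraining from scratch yields the same decision function.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: multiplier states
AT_ZERO, FREE, AT_C = 0, 1, 2


@njit(cache=True)
def _solve(X, y, C, alpha, state, kkt_tol, max_outer):  # pragma: no cover - numba
    n, d = X.shape
    Z = X * y.reshape(n, 1)
    b = 0.0
    # free-set bookkeeping with an incrementally maintained kernel matrix
    cap = d + 18
    if cap > n:
        cap = n
    idxF = np.empty(cap, np.int64)
    K = np.empty((cap, cap))
    nf = 0
    for i in range(n):
        if state[i] == FREE:
            if nf == cap:
                cap2 = cap * 2
                if cap2 > n:
                    cap2 = n
                idxF2 = np.empty(cap2, np.int64)
                K2 = np.empty((cap2, cap2))
                for a2 in range(nf):
                    idxF2[a2] = idxF[a2]
                    for b2 in range(nf):
                        K2[a2, b2] = K[a2, b2]
                idxF = idxF2
                K = K2
                cap = cap2
            # append row/col for i
            for jj in range(nf):
                s = 0.0
                for t in range(d):
                    s += Z[i, t] * Z[idxF[jj], t]
                K[nf, jj] = s
                K[jj, nf] = s
            s = 0.0
            for t in range(d):
                s += Z[i, t] * Z[i, t]
            K[nf, nf] = s
            idxF[nf] = i
            nf += 1
    wU = np.zeros(d)
    sU = 0.0
    for i in range(n):
        if state[i] == AT_C:
            for t in range(d):
                wU[t] += C * Z[i, t]
            sU += C * y[i]
    n_outer = 0
    while n_outer < max_outer:
        n_outer += 1
        full_step = True
        if nf > 0:
            M = np.empty((nf + 1, nf + 1))
            rhs = np.empty(nf + 1)
            for ii in range(nf):
                for jj in range(nf):
                    M[ii, jj] = K[ii, jj]
                M[ii, ii] += 1e-12 * (1.0 + K[ii, ii])
                M[ii, nf] = y[idxF[ii]]
                M[nf, ii] = y[idxF[ii]]
                s = 0.0
                for t in range(d):
                    s += Z[idxF[ii], t] * wU[t]
                rhs[ii] = 1.0 - s
            M[nf, nf] = 0.0
            rhs[nf] = -sU
            sol = np.linalg.solve(M, rhs)
            # step toward the subproblem optimum, stopping at the first bound
            tmax = 1.0
            blk = -1
            blk_state = AT_ZERO
            for ii in range(nf):
                i = idxF[ii]
                dv = sol[ii] - alpha[i]
                if dv < -1e-15 and alpha[i] + tmax * dv < 0.0:
                    tt = -alpha[i] / dv
                    if tt < tmax:
                        tmax = tt
                        blk = ii
                        blk_state = AT_ZERO
                elif dv > 1e-15 and alpha[i] + tmax * dv > C:
                    tt = (C - alpha[i]) / dv
                    if tt < tmax:
                        tmax = tt
                        blk = ii
                        blk_state = AT_C
            for ii in range(nf):
                i = idxF[ii]
                alpha[i] += tmax * (sol[ii] - alpha[i])
            if blk >= 0:
                i = idxF[blk]
                state[i] = blk_state
                alpha[i] = 0.0 if blk_state == AT_ZERO else C
                if blk_state == AT_C:
                    for t in range(d):
                        wU[t] += C * Z[i, t]
                    sU += C * y[i]
                # swap-remove position blk from the free set and kernel
                last = nf - 1
                if blk != last:
                    idxF[blk] = idxF[last]
                    for jj in range(nf):
                        K[blk, jj] = K[last, jj]
                    for jj in range(nf):
                        K[jj, blk] = K[jj, last]
                    K[blk, blk] = K[last, last]
                nf = last
                full_step = False
            else:
                b = sol[nf]
        else:
            # no free multipliers: place the bias mid-way between the active
            # KKT constraints of the bounded sets
            lo = -1.0e300
            hi = 1.0e300
            for i in range(n):
                m = 0.0
                for t in range(d):
                    m += X[i, t] * wU[t]
                if state[i] == AT_ZERO:
                    if y[i] > 0.0:
                        if 1.0 - m > lo:
                            lo = 1.0 - m
                    else:
                        if -1.0 - m < hi:
                            hi = -1.0 - m
                else:
                    if y[i] > 0.0:
                        if 1.0 - m < hi:
                            hi = 1.0 - m
                    else:
                        if -1.0 - m > lo:
                            lo = -1.0 - m
            if lo > -1.0e300 and hi < 1.0e300:
                b = 0.5 * (lo + hi)
            elif lo > -1.0e300:
                b = lo
            elif hi < 1.0e300:
                b = hi
            else:
                b = 0.0
        if not full_step:
            continue
        # full step taken: check global KKT conditions
        w = wU.copy()
        for ii in range(nf):
            i = idxF[ii]
            for t in range(d):
                w[t] += alpha[i] * Z[i, t]
        worst = -1
        worst_v = kkt_tol
        for i in range(n):
            m = 0.0
            for t in range(d):
                m += X[i, t] * w[t]
            g = y[i] * (m + b) - 1.0
            v = -g if state[i] == AT_ZERO else (g if state[i] == AT_C else -1.0)
            if v > worst_v:
                worst_v = v
                worst = i
        if worst < 0:
            return w, b, n_outer, True
        # admit the worst violator into the free set
        if state[worst] == AT_C:
            for t in range(d):
                wU[t] -= C * Z[worst, t]
            sU -= C * y[worst]
        state[worst] = FREE
        if nf == cap:
            cap2 = cap * 2
            if cap2 > n:
                cap2 = n
            idxF2 = np.empty(cap2, np.int64)
            K2 = np.empty((cap2, cap2))
            for a2 in range(nf):
                idxF2[a2] = idxF[a2]
                for b2 in range(nf):
                    K2[a2, b2] = K[a2, b2]
            idxF = idxF2
            K = K2
            cap = cap2
        for jj in range(nf):
            s = 0.0
            for t in range(d):
                s += Z[worst, t] * Z[idxF[jj], t]
            K[nf, jj] = s
            K[jj, nf] = s
        s = 0.0
        for t in range(d):
            s += Z[worst, t] * Z[worst, t]
        K[nf, nf] = s
        idxF[nf] = worst
        nf += 1
    # not converged within max_outer
    w = np.zeros(d)
    for i in range(n):
        if alpha[i] != 0.0:
            for t in range(d):
                w[t] += alpha[i] * Z[i, t]
    return w, b, n_outer, False


class LinearSvm:
    """Stateful exact linear SVM supporting warm-started re-solves.

    ``solve(X, y)`` returns ``(w, b)`` for the current data; the multiplier
    vector kept between calls must stay aligned with the rows of ``X``
    (use :meth:`insert_point` / :meth:`remove_point` when the buffer
    changes).  Falls back to a cold solve if the warm start fails to
    converge.
    """

    def __init__(self, C: float = 1.0, kkt_tol: float = 1e-10,
                 max_outer: int = 200000) -> None:
        self.C = float(C)
        self.kkt_tol = float(kkt_tol)
        self.max_outer = int(max_outer)
        self.alpha = np.empty(0)
        self.state = np.empty(0, np.int8)

    def reset(self) -> None:
        self.alpha = np.empty(0)
        self.state = np.empty(0, np.int8)

    def remove_point(self, index: int) -> None:
        self.alpha = np.delete(self.alpha, index)
        self.state = np.delete(self.state, index)

    def insert_point(self, index: int | None = None) -> None:
        """Register a new data row (default: appended) with zero multiplier."""
        index = self.alpha.size if index is None else index
        self.alpha = np.insert(self.alpha, index, 0.0)
        self.state = np.insert(self.state, index, AT_ZERO)

    def solve(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.ascontiguousarray(y, dtype=np.float64)
        n = X.shape[0]
        if y.shape[0] != n:
            raise ValueError("X and y length mismatch")
        if self.alpha.size != n:
            raise ValueError(
                f"multiplier state has {self.alpha.size} entries for {n} rows; "
                "track buffer edits with insert_point/remove_point or reset()"
            )
        if np.all(y > 0) or np.all(y < 0):
            raise ValueError("SVM needs both classes present")
        w, b, _, ok = _solve(X, y, self.C, self.alpha, self.state,
                             self.kkt_tol, self.max_outer)
        if not ok:  # cold restart as a safety net
            self.alpha[:] = 0.0
            self.state[:] = AT_ZERO
            w, b, _, ok = _solve(X, y, self.C, self.alpha, self.state,
                                 self.kkt_tol, self.max_outer)
            if not ok:
                raise RuntimeError("SVM active-set solver failed to converge")
        return w, float(b)


def batch_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0,
              kkt_tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Cold-start exact solve; the batch-retraining reference."""
    solver = LinearSvm(C=C, kkt_tol=kkt_tol)
    solver.alpha = np.zeros(len(y))
    solver.state = np.zeros(len(y), np.int8)
    return solver.solve(X, y)


# ---------------------------------------------------------------------------
# numba streaming engine for the adaptive decoder
# ---------------------------------------------------------------------------

@njit(cache=True)
def _append_fifo(Xb, ab, sb, nb, x):  # pragma: no cover - numba
    """FIFO append into a fixed-capacity buffer block; evicts the oldest row
    (and its multiplier) when full.  Returns the new fill count."""
    cap = Xb.shape[0]
    if nb == cap:
        for i in range(cap - 1):
            ab[i] = ab[i + 1]
            sb[i] = sb[i + 1]
            for t in range(Xb.shape[1]):
                Xb[i, t] = Xb[i + 1, t]
        nb = cap - 1
    for t in range(Xb.shape[1]):
        Xb[nb, t] = x[t]
    ab[nb] = 0.0
    sb[nb] = AT_ZERO
    return nb + 1


@njit(cache=True)
def _asvm_stream(X, labels, C, cap, stride, min_fill, standardize,
                 kkt_tol, max_outer, rest_code, move_code, boundary_code):
    # pragma: no cover - numba
    """Causal adaptive-SVM replay of a labeled frame stream.

    Returns (pred, w, b, mu, sd, ready, n_updates).  Stride frames first
    update the buffers and model, then the whole stride segment is
    classified with the updated model.
    """
    n, d = X.shape
    Xr = np.empty((cap, d)); ar = np.zeros(cap); sr = np.zeros(cap, np.int8)
    Xm = np.empty((cap, d)); am = np.zeros(cap); sm = np.zeros(cap, np.int8)
    nr = 0
    nm = 0
    w = np.zeros(d)
    b = 0.0
    mu = np.zeros(d)
    sd = np.ones(d)
    ready = False
    n_updates = 0
    pred = np.full(n, rest_code, np.int8)
    i = 0
    while i < n:
        lab = labels[i]
        if lab != boundary_code:
            # buffer update + exact retrain
            if lab == rest_code:
                nr = _append_fifo(Xr, ar, sr, nr, X[i])
            else:
                nm = _append_fifo(Xm, am, sm, nm, X[i])
            n_updates += 1
            if nr >= min_fill and nm >= min_fill:
                ntot = nr + nm
                W = np.empty((ntot, d))
                y = np.empty(ntot)
                alpha = np.empty(ntot)
                state = np.empty(ntot, np.int8)
                for k in range(nr):
                    y[k] = -1.0
                    alpha[k] = ar[k]
                    state[k] = sr[k]
                    for t in range(d):
                        W[k, t] = Xr[k, t]
                for k in range(nm):
                    y[nr + k] = 1.0
                    alpha[nr + k] = am[k]
                    state[nr + k] = sm[k]
                    for t in range(d):
                        W[nr + k, t] = Xm[k, t]
                if standardize:
                    for t in range(d):
                        s = 0.0
                        for k in range(ntot):
                            s += W[k, t]
                        m = s / ntot
                        v = 0.0
                        for k in range(ntot):
                            dv = W[k, t] - m
                            v += dv * dv
                        mu[t] = m
                        sd[t] = max(np.sqrt(v / ntot), 1e-12)
                for k in range(ntot):
                    for t in range(d):
                        W[k, t] = (W[k, t] - mu[t]) / sd[t]
                wn, bn, _, ok = _solve(W, y, C, alpha, state, kkt_tol, max_outer)
                if not ok:
                    for k in range(ntot):
                        alpha[k] = 0.0
                        state[k] = AT_ZERO
                    wn, bn, _, ok = _solve(W, y, C, alpha, state, kkt_tol, max_outer)
                w = wn
                b = bn
                ready = ok
                for k in range(nr):
                    ar[k] = alpha[k]
                    sr[k] = state[k]
                for k in range(nm):
                    am[k] = alpha[nr + k]
                    sm[k] = state[nr + k]
        if ready:
            stop = min(i + stride, n)
            for j in range(i, stop):
                dv = b
                for t in range(d):
                    dv += (X[j, t] - mu[t]) / sd[t] * w[t]
                pred[j] = move_code if dv > 0.0 else rest_code
        i += stride
    return pred, w, b, mu, sd, ready, n_updates
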