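"""Compiled inner loop for full-batch GD training.

The trainer's hot path — forward pass, exact gradients, parameter update
and noise injection — is a handful of small matrix products per step; at
the network sizes studied here Python call overhead dominates, so the
loop runs in a JIT-compiled kernel.  Noise is pregenerated in chunks by
the caller (numpy's PCG64 is much faster per Gaussian than per-call
generation inside the kernel) and streamed in.

Semantics match the reference trainer: metrics are recorded *before* the
update at each logged step plus once after the final update, and the
divergence guard trips when the (noisy) loss exceeds 10⁶ × its initial
value.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gd_chunk(
    X,            # (N, D) inputs
    Y,            # (N, K) targets
    mT,           # (D, H) input weights, transposed layout (mutated)
    b,            # (H,) bias (mutated)
    nT,           # (H, K) output weights, transposed layout (mutated)
    XT,           # (D, N) contiguous transpose of X
    eta,          # learning rate
    upd,          # (nsteps, P) pre-scaled update noise, or (0, 0) if none
    lab,          # (nsteps, N, K) pre-scaled label noise, or (0, 0, 0) if none
    step0,        # global index of the chunk's first step
    nsteps,       # steps in this chunk
    log_steps,    # sorted int64 array of global steps to record (before update)
    li,           # next index into log_steps
    raw_log,      # (L,) outputs ...
    af_log,
    fu_log,
    ckpts,        # (L, P) parameter snapshots
    initial,      # initial noisy loss (< 0 until set)
):
    N, D = X.shape
    K = Y.shape[1]
    H = b.shape[0]
    nk = N * K
    L = log_steps.shape[0]
    has_upd = upd.shape[0] > 0
    has_lab = lab.shape[0] > 0

    for s in range(nsteps):
        step = step0 + s
        pre = np.dot(X, mT)
        for i in range(N):
            for h in range(H):
                pre[i, h] += b[h]
        hidden = np.maximum(pre, 0.0)
        out = np.dot(hidden, nT)

        if li < L and step == log_steps[li]:
            sq = 0.0
            for i in range(N):
                for k in range(K):
                    r = out[i, k] - Y[i, k]
                    sq += r * r
            af = 0.0
            fu = 0.0
            for h in range(H):
                unit_on = False
                for i in range(N):
                    if hidden[i, h] > 1e-12:
                        af += 1.0
                        unit_on = True
                if unit_on:
                    fu += 1.0
            raw_log[li] = sq / nk
            af_log[li] = af / (N * H)
            fu_log[li] = fu / H
            p = 0
            for d in range(D):
                for h in range(H):
                    ckpts[li, p] = mT[d, h]
                    p += 1
            for h in range(H):
                ckpts[li, p] = b[h]
                p += 1
            for h in range(H):
                for k in range(K):
                    ckpts[li, p] = nT[h, k]
                    p += 1
            li += 1

        resid = out - Y
        if has_lab:
            for i in range(N):
                for k in range(K):
                    resid[i, k] += lab[s, i, k]
        noisy = 0.0
        for i in range(N):
            for k in range(K):
                noisy += resid[i, k] * resid[i, k]
                resid[i, k] *= 2.0 / nk
        noisy /= nk
        if initial < 0.0:
            initial = max(noisy, 1e-30)
        if not np.isfinite(noisy) or noisy > 1e6 * initial:
            return li, initial, step  # diverged

        gnT = np.dot(np.ascontiguousarray(hidden.T), resid)
        ghid = np.dot(resid, np.ascontiguousarray(nT.T))
        for i in range(N):
            for h in range(H):
                if pre[i, h] <= 0.0:
                    ghid[i, h] = 0.0
        gmT = np.dot(XT, ghid)

        if has_upd:
            p = 0
            for d in range(D):
                for h in range(H):
                    mT[d, h] += upd[s, p] - eta * gmT[d, h]
                    p += 1
            for h in range(H):
                gb = 0.0
                for i in range(N):
                    gb += ghid[i, h]
                b[h] += upd[s, p] - eta * gb
                p += 1
            for h in range(H):
                for k in range(K):
                    nT[h, k] += upd[s, p] - eta * gnT[h, k]
                    p += 1
        else:
            for d in range(D):
                for h in range(H):
                    mT[d, h] -= eta * gmT[d, h]
            for h in range(H):
                gb = 0.0
                for i in range(N):
                    gb += ghid[i, h]
                b[h] -= eta * gb
            for h in range(H):
                for k in range(K):
                    nT[h, k] -= eta * gnT[h, k]

    return li, initial, -1


def run_gd_loop(X, Y, m0, b0, n0, eta, sig_upd, sig_lab, steps, log_steps, seed,
                chunk=2048):
    """Drive :func:`gd_chunk` over the whole run with pregenerated noise.

    Returns (raw_log, af_log, fu_log, ckpts, diverged_at); parameters and
    metrics at each entry of ``log_steps`` (which must end with ``steps``,
    recorded after the final update).
    """
    N, D = X.shape
    K = Y.shape[1]
    H = b0.shape[0]
    P = D * H + H + H * K
    L = log_steps.shape[0]
    mT = np.ascontiguousarray(m0.T)
    b = b0.copy()
    nT = np.ascontiguousarray(n0.T)
    XT = np.ascontiguousarray(X.T)
    raw_log = np.empty(L)
    af_log = np.empty(L)
    fu_log = np.empty(L)
    ckpts = np.empty((L, P))
    rng = np.random.default_rng(seed)
    no_upd = np.empty((0, 0))
    no_lab = np.empty((0, 0, 0))

    li, initial, diverged_at = 0, -1.0, -1
    step0 = 0
    while step0 < steps and diverged_at < 0:
        ns = min(chunk, steps - step0)
        upd = rng.standard_normal((ns, P)) * sig_upd if sig_upd > 0 else no_upd
        lab = rng.standard_normal((ns, N, K)) * sig_lab if sig_lab > 0 else no_lab
        li, initial, diverged_at = gd_chunk(
            X, Y, mT, b, nT, XT, eta, upd, lab,
            step0, ns, log_steps, li, raw_log, af_log, fu_log, ckpts, initial,
        )
        step0 += ns
    if diverged_at < 0 and li == L - 1:
        # final record after the last update
        pre = X @ mT + b
        hidden = np.maximum(pre, 0.0)
        out = hidden @ nT
        raw_log[li] = float(np.mean((out - Y) ** 2))
        active = hidden > 1e-12
        af_log[li] = float(active.mean())
        fu_log[li] = float(active.any(axis=0).mean())
        ckpts[li] = np.concatenate([mT.ravel(), b, nT.ravel()])
    return raw_log, af_log, fu_log, ckpts, diverged_at
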