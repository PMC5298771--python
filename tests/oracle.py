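"""Independent naive per-window feature recomputation.

Deliberately written against the feature definitions with plain
per-window loops, numpy.trapezoid and numpy.std — none of the rolling
cumulative-sum machinery of the implementation — so agreement is a real
cross-check rather than a tautology.
"""

import numpy as np


def naive_feature(trace, code, nv=None):
    A = np.column_stack([trace.ax, trace.ay, trace.az])
    fs = trace.fs
    dt = 1.0 / fs
    n = len(A)

    if code == "C1":
        return np.array([np.linalg.norm(A[k]) for k in range(n)])
    if code == "C2":
        return np.array([np.hypot(A[k, 0], A[k, 2]) for k in range(n)])
    if code == "C4":
        return np.array(
            [np.arctan2(np.hypot(A[k, 0], A[k, 2]), -A[k, 1]) for k in range(n)]
        )

    assert nv is not None and nv >= 2
    out = []
    if code == "C6":
        for k in range(2 * nv - 1, n):
            prev = A[k - 2 * nv + 1 : k - nv + 1]
            cur = A[k - nv + 1 : k + 1]
            out.append(
                prev[:, 0].mean() * cur[:, 0].mean()
                + prev[:, 2].mean() * cur[:, 2].mean()
            )
        return np.array(out)

    for k in range(nv - 1, n):
        w = A[k - nv + 1 : k + 1]
        if code == "C3":
            out.append(np.linalg.norm([np.ptp(w[:, i]) for i in range(3)]))
        elif code == "C5":
            angles = np.arctan2(np.hypot(w[:, 0], w[:, 2]), w[:, 1])
            out.append(np.std(angles))
        elif code == "C7":
            out.append(np.linalg.norm(A[k] - A[k - nv + 1]) / ((nv - 1) * dt))
        elif code == "C8":
            out.append(np.hypot(np.std(w[:, 0]), np.std(w[:, 2])))
        elif code == "C9":
            out.append(np.sqrt(sum(np.std(w[:, i]) ** 2 for i in range(3))))
        elif code == "C10":
            out.append(
                sum(np.trapezoid(np.abs(w[:, i]), dx=dt) for i in range(3)) / nv
            )
        elif code == "C11":
            out.append(
                (np.trapezoid(np.abs(w[:, 0]), dx=dt) + np.trapezoid(np.abs(w[:, 2]), dx=dt))
                / nv
            )
        elif code == "C12":
            out.append(np.trapezoid(np.linalg.norm(w, axis=1), dx=1.0))
        elif code == "C13":
            out.append(np.trapezoid(np.hypot(w[:, 0], w[:, 2]), dx=1.0))
        elif code == "C14":
            out.append(
                np.hypot(np.trapezoid(w[:, 0], dx=dt), np.trapezoid(w[:, 2], dx=dt)) / nv
            )
        else:
            raise ValueError(code)
    return np.array(out)
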