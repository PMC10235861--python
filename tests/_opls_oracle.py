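"""Independent reference implementation of single-response NIPALS O-PLS.

A deliberately separate transcription of the orthogonal-projections
recursion used as an oracle in the tests.  It shares no code with the
package: scaling is inlined, the predictive weight is recomputed from the
deflated matrix in every round (mathematically equivalent because the
covariance X'y is invariant under y-orthogonal deflation, but a different
floating-point path), and prediction walks test rows one at a time.
"""

import numpy as np


def opls_reference_predictions(X_train, y_train, X_test, n_ortho):
    """Fit O-PLS (1 predictive + n_ortho orthogonal) and predict X_test."""
    X_train = np.array(X_train, dtype=float)
    y_train = np.array(y_train, dtype=float)

    x_mean = X_train.mean(axis=0)
    y_mean = y_train.mean()
    y_sd = y_train.std(ddof=1)
    E = X_train - x_mean
    f = (y_train - y_mean) / y_sd

    ortho_weights = []
    ortho_loadings = []
    for _ in range(n_ortho):
        w = E.T @ f
        w = w / np.sqrt(np.sum(w * w))
        t = E @ w
        p = E.T @ t / np.dot(t, t)
        w_orth = p - np.dot(w, p) * w
        w_orth = w_orth / np.sqrt(np.sum(w_orth * w_orth))
        t_orth = E @ w_orth
        p_orth = E.T @ t_orth / np.dot(t_orth, t_orth)
        E = E - np.outer(t_orth, p_orth)
        ortho_weights.append(w_orth)
        ortho_loadings.append(p_orth)

    w = E.T @ f
    w = w / np.sqrt(np.sum(w * w))
    t = E @ w
    q = np.dot(f, t) / np.dot(t, t)

    preds = []
    for row in np.atleast_2d(np.array(X_test, dtype=float)):
        e = row - x_mean
        for w_orth, p_orth in zip(ortho_weights, ortho_loadings):
            e = e - np.dot(e, w_orth) * p_orth
        preds.append(y_mean + y_sd * q * np.dot(e, w))
    return np.array(preds)
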