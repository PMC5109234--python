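"""Independent reference implementations used only to check the package.

These are direct transcriptions of the defining formulas — per-template
counting for ApEn and textbook split-plot sums of squares for the mixed
ANOVA — kept deliberately separate from the package's vectorized code
paths.
"""

import numpy as np


def apen_bruteforce(x, m=2, r_factor=0.2, lag=10):
    """ApEn by direct template counting (self-matches included)."""
    x = np.asarray(x, dtype=float)
    r = r_factor * np.std(x)

    def phi(mm):
        n = len(x) - (mm - 1) * lag
        templates = np.array(
            [x[i: i + (mm - 1) * lag + 1: lag] for i in range(n)]
        )
        logs = np.empty(n)
        for i in range(n):
            d = np.abs(templates - templates[i]).max(axis=1)
            logs[i] = np.log(np.count_nonzero(d <= r) / n)
        return logs.mean()

    return phi(m) - phi(m + 1)


def mixed_anova_2within(Y):
    """Split-plot ANOVA for Y[group, subject, A, B]: textbook cell-mean SS.

    Returns {effect: F} for the seven testable effects.
    """
    g, n, a, b = Y.shape
    m = Y.mean()
    m_g = Y.mean(axis=(1, 2, 3))
    m_gs = Y.mean(axis=(2, 3))
    m_a = Y.mean(axis=(0, 1, 3))
    m_b = Y.mean(axis=(0, 1, 2))
    m_ga = Y.mean(axis=(1, 3))
    m_gb = Y.mean(axis=(1, 2))
    m_ab = Y.mean(axis=(0, 1))
    m_gab = Y.mean(axis=1)
    m_gsa = Y.mean(axis=3)
    m_gsb = Y.mean(axis=2)

    ss_g = n * a * b * np.sum((m_g - m) ** 2)
    ss_s = a * b * np.sum((m_gs - m_g[:, None]) ** 2)
    ss_a = g * n * b * np.sum((m_a - m) ** 2)
    ss_ga = n * b * np.sum((m_ga - m_g[:, None] - m_a[None, :] + m) ** 2)
    ss_err_a = b * np.sum(
        (m_gsa - m_gs[:, :, None] - m_ga[:, None, :] + m_g[:, None, None]) ** 2
    )
    ss_b = g * n * a * np.sum((m_b - m) ** 2)
    ss_gb = n * a * np.sum((m_gb - m_g[:, None] - m_b[None, :] + m) ** 2)
    ss_err_b = a * np.sum(
        (m_gsb - m_gs[:, :, None] - m_gb[:, None, :] + m_g[:, None, None]) ** 2
    )
    ss_ab = g * n * np.sum(
        (m_ab - m_a[:, None] - m_b[None, :] + m) ** 2
    )
    ss_gab = n * np.sum(
        (
            m_gab
            - m_ga[:, :, None]
            - m_gb[:, None, :]
            - m_ab[None, :, :]
            + m_a[None, :, None]
            + m_b[None, None, :]
            + m_g[:, None, None]
            - m
        )
        ** 2
    )
    ss_err_ab = np.sum(
        (
            Y
            - m_gsa[:, :, :, None]
            - m_gsb[:, :, None, :]
            - m_gab[:, None, :, :]
            + m_gs[:, :, None, None]
            + m_ga[:, None, :, None]
            + m_gb[:, None, None, :]
            - m_g[:, None, None, None]
        )
        ** 2
    )

    def f(ss_eff, df_eff, ss_err, df_err):
        return (ss_eff / df_eff) / (ss_err / df_err)

    return {
        "G": f(ss_g, g - 1, ss_s, g * (n - 1)),
        "A": f(ss_a, a - 1, ss_err_a, g * (n - 1) * (a - 1)),
        "GxA": f(ss_ga, (g - 1) * (a - 1), ss_err_a, g * (n - 1) * (a - 1)),
        "B": f(ss_b, b - 1, ss_err_b, g * (n - 1) * (b - 1)),
        "GxB": f(ss_gb, (g - 1) * (b - 1), ss_err_b, g * (n - 1) * (b - 1)),
        "AxB": f(ss_ab, (a - 1) * (b - 1), ss_err_ab,
                 g * (n - 1) * (a - 1) * (b - 1)),
        "GxAxB": f(ss_gab, (g - 1) * (a - 1) * (b - 1), ss_err_ab,
                   g * (n - 1) * (a - 1) * (b - 1)),
    }


def design_to_frame(Y, import_pd=True):
    """Tidy long-format frame for Y[group, subject, A, B]."""
    import pandas as pd

    g, n, a, b = Y.shape
    rows = []
    for gi in range(g):
        for si in range(n):
            for ai in range(a):
                for bi in range(b):
                    rows.append(
                        {
                            "subject": f"g{gi}s{si}",
                            "group": f"g{gi}",
                            "A": f"a{ai}",
                            "B": f"b{bi}",
                            "value": Y[gi, si, ai, bi],
                        }
                    )
    return pd.DataFrame(rows)
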