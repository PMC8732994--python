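"""Independent brute-force oracles, kept deliberately separate from the
package implementation paths they check."""

import math

import numpy as np

POSITIVE = [
    "amusement", "awe", "content", "joy", "gratitude",
    "hope", "interest", "love", "pride", "surprise",
]
NEGATIVE = [
    "anger", "shame", "fear", "disgust",
    "embarrassment", "guilt", "sadness", "contempt",
]
ITEMS = POSITIVE + NEGATIVE


def diversity_oracle(ratings_by_item: dict) -> dict:
    """Literal step-by-step emodiversity computation (scalar math only).

    1. rescale 0..4 -> -2..2 and logistic-transform each rating;
    2. divide each intensity by the sum over all 18;
    3-4. p * ln(p) per emotion;
    5. sum over all / positive / negative items; negate so higher = more
    diverse.
    """
    intensities = {}
    for item in ITEMS:
        x = ratings_by_item[item] - 2
        intensities[item] = 1.0 / (1.0 + math.exp(-x))
    total_intensity = sum(intensities.values())
    p = {item: intensities[item] / total_intensity for item in ITEMS}
    terms = {item: p[item] * math.log(p[item]) for item in ITEMS}
    return {
        "total": -sum(terms[i] for i in ITEMS),
        "positive": -sum(terms[i] for i in POSITIVE),
        "negative": -sum(terms[i] for i in NEGATIVE),
        "proportions": p,
        "mean_positive": sum(ratings_by_item[i] for i in POSITIVE) / len(POSITIVE),
        "mean_negative": sum(ratings_by_item[i] for i in NEGATIVE) / len(NEGATIVE),
    }


def welch_oracle(m1, s1, n1, m2, s2, n2):
    """Direct Welch formulas: t, Welch-Satterthwaite df."""
    se2 = s1**2 / n1 + s2**2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1))
    return t, df


def yates_oracle(table):
    """N * (max(|ad - bc| - N/2, 0))^2 / (r1 r2 c1 c2)."""
    (a, b), (c, d) = table
    n = a + b + c + d
    num = max(abs(a * d - b * c) - n / 2, 0.0) ** 2 * n
    return num / ((a + b) * (c + d) * (a + c) * (b + d))


def chi2_uncorrected_oracle(table):
    (a, b), (c, d) = table
    n = a + b + c + d
    return (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))


def ols_normal_equations(y, X_no_intercept):
    """OLS coefficients via the normal equations, intercept first."""
    X = np.column_stack([np.ones(len(y)), X_no_intercept])
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))


def pearson_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
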