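import numpy as np
import pytest

from lymphosteroid import ExpressionMatrix, GeneAnnotation


def brute_force_ranks(v):
    """Mid-ranks by explicit sorting with tie averaging (test oracle)."""
    v = list(v)
    order = sorted(range(len(v)), key=lambda i: v[i])
    r = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            r[order[k]] = avg
        i = j + 1
    return r


def brute_force_spearman(x, y):
    """Rank-then-Pearson Spearman oracle, independent of scipy."""
    rx, ry = brute_force_ranks(x), brute_force_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx) ** 0.5
    dy = sum((b - my) ** 2 for b in ry) ** 0.5
    return num / (dx * dy)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    values = rng.lognormal(1.0, 1.0, size=(5, 20))
    return ExpressionMatrix(
        [f"g{i}" for i in range(5)], [f"c{j}" for j in range(20)], values
    )


@pytest.fixture
def annotation():
    return GeneAnnotation(
        {
            "Ly6C2": "surface_receptor",
            "Ly6C1": "surface_receptor",
            "Il2ra": "surface_receptor",
            "Il10": "cytokine",
            "Tgfb1": "cytokine",
            "Gata3": "transcription_factor",
        },
        {"Il10": True, "Tgfb1": True},
    )
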