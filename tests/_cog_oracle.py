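"""Brute-force Mamdani/COG oracle, independent of the package's inference path.

Memberships are recomputed from the raw formulas, rules are fired with
explicit Python min/max loops, the aggregate is built pointwise on a dense
grid and the centroid is integrated with ``numpy.trapezoid``.
"""

import math

import numpy as np

GRID = np.linspace(0.0, 100.0, 20001)


def membership(mf, x):
    x = min(max(x, mf.domain[0]), mf.domain[1])
    if mf.kind == "linear_two_point":
        (x0, y0), (x1, y1) = mf.params
        return min(1.0, max(0.0, y0 + (y1 - y0) * (x - x0) / (x1 - x0)))
    if mf.kind == "gaussian":
        c, s = mf.params
        return math.exp(-((x - c) ** 2) / (2 * s * s))
    c1, c2, s = mf.params
    return max(
        math.exp(-((x - c1) ** 2) / (2 * s * s)),
        math.exp(-((x - c2) ** 2) / (2 * s * s)),
    )


def cog_score(component, crisp_inputs):
    """Centroid of the max-aggregated, clipped consequent sets; 50 if empty."""
    variables = {v.name: v for v in component.inputs}
    aggregate = np.zeros_like(GRID)
    for rule in component.rules:
        activation = min(
            membership(variables[var].terms[label], crisp_inputs[var])
            for var, label in rule.antecedents
        )
        consequent = component.output.terms[rule.consequent[1]]
        clipped = np.minimum([membership(consequent, g) for g in GRID], activation)
        aggregate = np.maximum(aggregate, clipped)
    area = np.trapezoid(aggregate, GRID)
    if area == 0.0:
        return 50.0
    return float(np.trapezoid(aggregate * GRID, GRID) / area)


def random_inputs(component, rng):
    return {
        v.name: float(rng.uniform(v.domain[0], v.domain[1])) for v in component.inputs
    }
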