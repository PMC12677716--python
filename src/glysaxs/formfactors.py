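"""X-ray atomic form factors f(q) for the supported elements.

The standard four-Gaussian-plus-constant parameterization from the
International Tables is shipped as a JSON data file; ``f(0)`` equals the
element's electron number.  Hydrogens are treated explicitly — there is
no implicit-hydrogen merging here (callers may drop H atoms themselves
if they want a heavy-atom approximation).
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = ["supported_elements", "atomic_form_factor", "form_factor_table"]


@lru_cache(maxsize=1)
def _coefficients() -> dict[str, dict]:
    text = resources.files("glysaxs").joinpath("data/form_factors.json").read_text()
    raw = json.loads(text)
    return {
        el: {"a": np.asarray(v["a"]), "b": np.asarray(v["b"]), "c": float(v["c"])}
        for el, v in raw.items()
        if not el.startswith("_")
    }


def supported_elements() -> tuple[str, ...]:
    return tuple(sorted(_coefficients()))


def atomic_form_factor(element: str, q) -> np.ndarray | float:
    """Evaluate f(q) in electrons for one element.

    ``q`` is the momentum transfer in Å⁻¹ (scalar or array, q ≥ 0).
    Raises ``KeyError`` for unsupported elements, listing the supported set.
    """
    coeff = _coefficients()
    el = element.strip().capitalize()
    if el not in coeff:
        raise KeyError(
            f"element {element!r} has no form-factor entry; supported: {supported_elements()}"
        )
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    s2 = (q / (4.0 * np.pi)) ** 2  # (sin(theta)/lambda)^2
    c = coeff[el]
    f = c["c"] + np.sum(c["a"] * np.exp(-np.outer(s2.ravel(), c["b"])), axis=1)
    return float(f[0]) if q.ndim == 0 else f.reshape(q.shape)


def form_factor_table(elements, q_grid: np.ndarray) -> np.ndarray:
    """Per-atom form factors on a grid, shape ``(n_q, n_atoms)``.

    ``elements`` is the per-atom element array; identical elements share
    one evaluation.
    """
    elements = np.asarray(elements, dtype="U2")
    q_grid = np.asarray(q_grid, dtype=float)
    out = np.empty((len(q_grid), len(elements)))
    for el in np.unique(elements):
        out[:, elements == el] = atomic_form_factor(el, q_grid)[:, None]
    return out
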