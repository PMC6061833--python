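"""Pluggable contour (vector) filters.

Filters operate directly on the ordered node array of an :class:`Outline`
and are discoverable by name through an open registry, so third-party
filters can be dropped in without touching the pipeline.  A filter is a
callable ``nodes (N,2) -> nodes (M,2)``; its output is re-validated against
the Outline invariants and a :class:`FilterContractError` names the filter
if it broke them.
"""

from __future__ import annotations

import numpy as np

from .contours import Outline
from .errors import FilterContractError, MorphodynError, ParameterError

#: name -> factory(**params) -> callable(nodes) registry
FILTER_REGISTRY: dict[str, callable] = {}


def register_filter(name: str):
    """Decorator registering a filter factory under ``name``."""
    def deco(factory):
        FILTER_REGISTRY[name] = factory
        return factory
    return deco


def make_filter(name: str, **params):
    if name not in FILTER_REGISTRY:
        raise ParameterError(
            f"unknown contour filter {name!r}; registered: {sorted(FILTER_REGISTRY)}")
    f = FILTER_REGISTRY[name](**params)
    f.filter_name = name
    return f


def apply_contour_filter(outline: Outline, filt) -> Outline:
    """Apply a filter callable to an outline, re-validating the invariants."""
    name = getattr(filt, "filter_name", getattr(filt, "__name__", repr(filt)))
    new_nodes = np.asarray(filt(outline.nodes.copy()), dtype=float)
    try:
        return Outline(new_nodes, frame_index=outline.frame_index)
    except MorphodynError as exc:
        raise FilterContractError(name, str(exc)) from exc


@register_filter("running_mean")
def _running_mean(window: int = 5):
    """Circular windowed mean of the node coordinates (odd window).

    ``window=1`` is the identity.  Smoothing strictly shortens the perimeter
    of any non-degenerate polygon (Jensen on the chord lengths).
    """
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ParameterError("running_mean window must be a positive odd integer")

    def f(nodes):
        if window == 1:
            return nodes
        n = nodes.shape[0]
        half = window // 2
        idx = (np.arange(n)[:, None] + np.arange(-half, half + 1)[None, :]) % n
        return nodes[idx].mean(axis=1)
    return f


@register_filter("protrusion_remove")
def _protrusion_remove(t_neck: float = 3.0, k: float = 3.0):
    """Remove boundary subpaths pinched off by a narrow neck.

    A subpath is removed when the straight distance between its two flanking
    nodes (the neck width) is below ``t_neck`` while its arc length exceeds
    ``k * t_neck``; the span is replaced by the straight neck segment.  The
    scan is greedy from node 0 and repeats until no candidate remains, which
    makes the result deterministic.
    """
    if t_neck <= 0 or k <= 0:
        raise ParameterError("t_neck and k must be > 0")

    def f(nodes):
        changed = True
        while changed and nodes.shape[0] > 3:
            changed = False
            n = nodes.shape[0]
            el = np.linalg.norm(np.roll(nodes, -1, axis=0) - nodes, axis=1)
            P = el.sum()
            for i in range(n):
                arc = 0.0
                j = i
                while True:
                    arc += el[j % n]
                    j += 1
                    if arc > P / 2:
                        break
                    d = np.linalg.norm(nodes[i] - nodes[j % n])
                    if d < t_neck and arc > k * t_neck:
                        keep = np.ones(n, bool)
                        span = np.arange(i + 1, j) % n
                        keep[span] = False
                        if keep.sum() >= 3:
                            nodes = nodes[keep]
                            changed = True
                        break
                if changed:
                    break
        return nodes
    return f


def parse_filter_spec(spec: str):
    """Parse a CLI filter spec ``name:param=value,param=value``."""
    if ":" in spec:
        name, rest = spec.split(":", 1)
        params = {}
        for tok in rest.split(","):
            if not tok:
                continue
            key, _, val = tok.partition("=")
            try:
                params[key] = int(val)
            except ValueError:
                try:
                    params[key] = float(val)
                except ValueError:
                    params[key] = val
    else:
        name, params = spec, {}
    return make_filter(name, **params)
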