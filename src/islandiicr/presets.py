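"""Shipped parameter-space presets."""

from __future__ import annotations

import json
from importlib import resources

from .demography import Bounds

__all__ = ["human_bounds"]


def human_bounds(n_components: int) -> Bounds:
    """Inference bounds used for fitting human PSMC curves.

    Times are in generations (roughly 10 kya to 10 Mya at 25 years per
    generation), migration rates in [1/20, 20], deme sizes fixed to 1,
    and the reference size N in [1e2, 1e4] haploid genes.
    """
    payload = json.loads(
        resources.files("islandiicr").joinpath("data/human_bounds.json").read_text()
    )
    gamma = n_components - 1
    return Bounds.uniform(
        gamma,
        n=tuple(payload["n_range"]),
        t=tuple(payload["t_range"]),
        M=tuple(payload["M_range"]),
        s=tuple(payload["s_range"]),
        N=tuple(payload["N_range"]),
    )
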