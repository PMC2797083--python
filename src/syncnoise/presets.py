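"""Access to the packaged model and experiment presets (``presets.yaml``)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .models import (
    InvalidInputError,
    OscillatorModel,
    fitzhugh_nagumo,
    hindmarsh_rose,
)

__all__ = ["load_presets", "model_from_preset", "experiment_preset"]

_FACTORIES = {
    "fitzhugh_nagumo": fitzhugh_nagumo,
    "hindmarsh_rose": hindmarsh_rose,
}


@lru_cache(maxsize=1)
def load_presets() -> dict:
    """Parse and cache the packaged preset file."""
    text = resources.files("syncnoise").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def model_from_preset(name: str, overrides: dict | None = None) -> OscillatorModel:
    """Build a model from its preset entry, with optional parameter overrides."""
    presets = load_presets()["models"]
    if name not in presets:
        raise InvalidInputError(f"unknown model preset {name!r}")
    entry = presets[name]
    params = dict(entry["params"])
    if overrides:
        params.update(overrides)
    return _FACTORIES[name](
        params,
        noise_mask=tuple(entry["noise_mask"]),
        coupling_mask=tuple(entry["coupling_mask"]),
        input_mask=tuple(entry["input_mask"]),
    )


def experiment_preset(name: str) -> dict:
    """Return a copy of one experiment's default conditions."""
    presets = load_presets()["experiments"]
    if name not in presets:
        raise InvalidInputError(
            f"unknown experiment preset {name!r}; available: {sorted(presets)}"
        )
    import copy

    return copy.deepcopy(presets[name])
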