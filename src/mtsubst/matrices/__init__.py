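"""Bundled published amino-acid substitution models in PAML .dat layout.

``load_model("LG")`` returns any bundled model; see ``available()`` and
the provenance notes in this directory's README.
"""

from __future__ import annotations

from importlib import resources

from ..models import SubstitutionModel, read_model

__all__ = ["available", "load_model"]


def _data_dir():
    return resources.files(__name__)


def available() -> list[str]:
    """Names of the bundled models."""
    return sorted(p.name[:-4] for p in _data_dir().iterdir() if p.name.endswith(".dat"))


def load_model(name: str) -> SubstitutionModel:
    """Load a bundled model by name (case-insensitive), e.g. ``"WAG"``."""
    matches = {m.lower(): m for m in available()}
    key = name.lower()
    if key not in matches:
        raise KeyError(f"no bundled model {name!r}; available: {', '.join(available())}")
    actual = matches[key]
    with resources.as_file(_data_dir() / f"{actual}.dat") as path:
        return read_model(path, name=actual)
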