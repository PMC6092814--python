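"""YAML configuration loading for geometry and surrogate-flow blocks."""

from __future__ import annotations

from pathlib import Path

import yaml

from .flow import SurrogateFlowSpec
from .geometry import WellGeometry

__all__ = ["load_config"]


def load_config(path) -> tuple[WellGeometry, SurrogateFlowSpec]:
    """Read a YAML config with ``geometry`` and ``flow`` blocks.

    Block keys mirror the :class:`WellGeometry` and
    :class:`SurrogateFlowSpec` field names; missing keys take the field
    defaults, unknown keys are rejected.
    """
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    geo_kwargs = raw.get("geometry", {}) or {}
    flow_kwargs = raw.get("flow", {}) or {}
    geo_fields = set(WellGeometry.__dataclass_fields__)
    flow_fields = set(SurrogateFlowSpec.__dataclass_fields__)
    bad = set(geo_kwargs) - geo_fields
    if bad:
        raise ValueError(f"unknown geometry keys: {sorted(bad)}")
    bad = set(flow_kwargs) - flow_fields
    if bad:
        raise ValueError(f"unknown flow keys: {sorted(bad)}")
    return WellGeometry(**geo_kwargs), SurrogateFlowSpec(**flow_kwargs)
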