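"""Growth-condition constraint sets.

A :class:`ConditionConfig` names the medium: per exchange metabolite a pair
of uptake bounds (positive magnitudes, mmol/mmol dry cell/h; the photon
bound is carried numerically in its native μEinstein/m²/s).  Exchange
reactions are written in the export direction, so the engine maps an uptake
pair ``(lo, hi)`` to exchange flux bounds ``(-hi, -lo)``: a fixed pair
forces uptake, a ``(0, hi)`` pair allows up to ``hi``, and an explicit
``(0, 0)`` closes the exchange entirely.  Metabolites not mentioned default
to zero uptake with secretion open; metabolites listed as *free* may enter
or leave without limit (water, protons, common ions).

Built-in presets encode the three trophic study conditions:

========== =========== ========== ========= ========= ========= ==========
condition  bicarbonate phosphate  nitrate   sulfate   glucose   photons
========== =========== ========== ========= ========= ========= ==========
autotroph  0.20 fixed  0-0.0056   0-0.040   0-0.0014  0         0-100
heterotr.  0           0-0.0056   0-0.040   0-0.0014  0.017 fix 0
mixotroph  0.20 fixed  0-0.0056   0-0.040   0-0.0014  0.017 fix 0-100
========== =========== ========== ========= ========= ========= ==========
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

DEFAULT_FREE_EXCHANGES = frozenset({"h2o", "h", "na1", "mg2", "zn2", "fe2", "k", "cl"})

_COMMON_UPTAKES = {
    "pi": (0.0, 0.0056),
    "no3": (0.0, 0.040),
    "so4": (0.0, 0.0014),
}

_PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "autotrophic": {
        "hco3": (0.20, 0.20),
        "glc": (0.0, 0.0),
        "photon": (0.0, 100.0),
        **_COMMON_UPTAKES,
    },
    "heterotrophic": {
        "hco3": (0.0, 0.0),
        "glc": (0.017, 0.017),
        "photon": (0.0, 0.0),
        **_COMMON_UPTAKES,
    },
    "mixotrophic": {
        "hco3": (0.20, 0.20),
        "glc": (0.017, 0.017),
        "photon": (0.0, 100.0),
        **_COMMON_UPTAKES,
    },
}

PRESET_NAMES = tuple(_PRESETS)


@dataclass(frozen=True)
class ConditionConfig:
    """A named set of exchange uptake bounds (positive magnitudes)."""

    name: str
    uptakes: dict[str, tuple[float, float]] = field(default_factory=dict)
    free: frozenset[str] = DEFAULT_FREE_EXCHANGES

    def __post_init__(self):
        for key, (lo, hi) in self.uptakes.items():
            if lo > hi:
                raise ValueError(f"uptake bounds for {key!r} have lower {lo} > upper {hi}")
            if lo < 0:
                raise ValueError(f"uptake bounds for {key!r} must be non-negative magnitudes")

    def override(self, **uptakes: tuple[float, float]) -> "ConditionConfig":
        """A copy with the given uptake pairs replaced or added."""
        merged = dict(self.uptakes)
        merged.update(uptakes)
        return replace(self, uptakes=merged)


def condition_preset(name: str) -> ConditionConfig:
    """One of the built-in trophic presets (see module docstring)."""
    try:
        uptakes = _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(_PRESETS)}") from None
    return ConditionConfig(name=name, uptakes=dict(uptakes))


def read_condition_config(path: str | Path) -> ConditionConfig:
    """Read a plain-text condition file.

    Format: optional ``preset = <name>`` to start from a preset, optional
    ``name = <label>``, then one ``<key> = <lo>, <hi>`` line per exchange
    metabolite and an optional ``free = k1, k2, ...`` line.  Values given
    in the file override the preset.
    """
    path = Path(path)
    base: ConditionConfig | None = None
    name = path.stem
    uptakes: dict[str, tuple[float, float]] = {}
    free: frozenset[str] | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key == "preset":
            base = condition_preset(value)
        elif key == "name":
            name = value
        elif key == "free":
            free = frozenset(v.strip() for v in value.split(",") if v.strip())
        else:
            parts = [v.strip() for v in value.split(",")]
            if len(parts) == 1:
                lo = hi = float(parts[0])
            elif len(parts) == 2:
                lo, hi = float(parts[0]), float(parts[1])
            else:
                raise ValueError(f"{path}:{lineno}: bound pair must be 'lo, hi', got {value!r}")
            uptakes[key] = (lo, hi)
    merged = dict(base.uptakes) if base is not None else {}
    merged.update(uptakes)
    return ConditionConfig(
        name=name,
        uptakes=merged,
        free=free if free is not None else (base.free if base else DEFAULT_FREE_EXCHANGES),
    )
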