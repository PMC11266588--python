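"""Plain-text run configuration mapping onto module parameters.

The segmentation tool's tunables (iterations, kernel size of the active
contour, seed radius, regularisation weights, filter settings) live in a
TOML file; a converter also reads the spreadsheet schema
(``Segmentation_Parameters.xlsx`` with parameter/value columns) for
compatibility with the original tool's configuration.  Unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import tomllib
from dataclasses import fields as dataclass_fields
from pathlib import Path

from .enhancement import EnhancementParams
from .lgdf import LGDFParams
from .preprocessing import FilterParams

__all__ = ["RunConfig", "load_config"]

_SECTIONS = {
    "segmentation": LGDFParams,
    "filter": FilterParams,
    "enhancement": EnhancementParams,
}


class RunConfig:
    """Validated bundle of all module parameter sets."""

    def __init__(
        self,
        segmentation: LGDFParams | None = None,
        filter: FilterParams | None = None,
        enhancement: EnhancementParams | None = None,
        verbosity: int = 0,
    ) -> None:
        self.segmentation = segmentation or LGDFParams()
        self.filter = filter or FilterParams()
        self.enhancement = enhancement or EnhancementParams()
        self.verbosity = verbosity

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        kwargs = {}
        extra = set(data) - set(_SECTIONS) - {"verbosity"}
        if extra:
            raise KeyError(f"unknown config sections: {sorted(extra)}")
        for section, klass in _SECTIONS.items():
            payload = dict(data.get(section, {}))
            allowed = {f.name for f in dataclass_fields(klass)}
            unknown = set(payload) - allowed
            if unknown:
                raise KeyError(f"unknown keys in [{section}]: {sorted(unknown)}")
            for key in ("seed_center", "clahe_tiles"):
                if key in payload and isinstance(payload[key], list):
                    payload[key] = tuple(payload[key])
            kwargs[section] = klass(**payload)
        return cls(verbosity=int(data.get("verbosity", 0)), **kwargs)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_mapping(tomllib.load(fh))

    @classmethod
    def from_workbook(cls, path: str | Path) -> "RunConfig":
        """Read the spreadsheet configuration schema (parameter, value)."""
        import pandas as pd

        frame = pd.read_excel(path)
        frame.columns = [str(c).strip().lower() for c in frame.columns]
        if not {"parameter", "value"} <= set(frame.columns):
            raise IOError("expected 'parameter' and 'value' columns")
        mapping = {"iterations": "iterations", "kernel_size": "kernel_sigma",
                   "kernel_sigma": "kernel_sigma", "radius": "seed_radius",
                   "seed_radius": "seed_radius"}
        seg: dict = {}
        for _, row in frame.iterrows():
            key = str(row["parameter"]).strip().lower()
            if key not in mapping:
                raise KeyError(f"unknown segmentation parameter: {key!r}")
            value = float(row["value"])
            seg[mapping[key]] = int(value) if mapping[key] == "iterations" else value
        return cls.from_mapping({"segmentation": seg})

    def to_toml(self, path: str | Path) -> None:
        """Write the effective configuration (round-trips with from_toml)."""
        lines = [f"verbosity = {self.verbosity}", ""]
        for section, obj in (
            ("segmentation", self.segmentation),
            ("filter", self.filter),
            ("enhancement", self.enhancement),
        ):
            lines.append(f"[{section}]")
            for f in dataclass_fields(type(obj)):
                value = getattr(obj, f.name)
                if value is None:
                    continue
                if isinstance(value, tuple):
                    lines.append(f"{f.name} = {list(value)!r}")
                elif isinstance(value, bool):
                    lines.append(f"{f.name} = {str(value).lower()}")
                elif isinstance(value, str):
                    lines.append(f'{f.name} = "{value}"')
                else:
                    lines.append(f"{f.name} = {value!r}")
            lines.append("")
        Path(path).write_text("\n".join(lines))


def load_config(path: str | Path | None) -> RunConfig:
    """Load a TOML or spreadsheet configuration; defaults when path is None."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return RunConfig.from_workbook(path)
    return RunConfig.from_toml(path)
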