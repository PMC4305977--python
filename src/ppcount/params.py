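"""Threshold parameters for HSI positive-pixel classification.

The classifier is controlled by a hue window (center + total width on the
circular [0, 1) hue axis), a minimum color saturation, and four intensity
cut points that partition stained pixels into strong / medium / weak
positive bins, with everything at or above ``iwp_high`` treated as
background. Unstained pixels darker than ``inp_high`` count as negative
(counterstained) tissue; the sentinel ``inp_high = -1`` ties that ceiling
to ``iwp_high``.

The shipped defaults are the vendor positive-pixel-count settings for DAB
brown on 8-bit RGB scans: hue 0.1 +/- 0.25, saturation >= 0.5, intensity
bins 0 / 70 / 70 / 230. Note the equal middle cut points make the
medium-positive bin empty by construction.
"""

from __future__ import annotations

import configparser
import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

__all__ = ["PixelClassParams", "default_params", "load_params"]

_PARAM_KEYS = (
    "hue_value",
    "hue_width",
    "saturation_threshold",
    "iwp_high",
    "ip_high",
    "isp_high",
    "isp_low",
    "inp_high",
)


@dataclass(frozen=True)
class PixelClassParams:
    """HSI threshold set governing pixel classification.

    Intensities are on the 8-bit scale [0, 255]; hue and saturation are
    unitless on [0, 1). ``hue_width`` is the TOTAL breadth of the hue
    window, i.e. the window is ``hue_value +/- hue_width / 2`` on the
    circle.
    """

    hue_value: float = 0.1
    hue_width: float = 0.5
    saturation_threshold: float = 0.5
    iwp_high: float = 230.0
    ip_high: float = 70.0
    isp_high: float = 70.0
    isp_low: float = 0.0
    inp_high: float = -1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hue_value < 1.0:
            raise ValueError(f"hue_value must be in [0, 1), got {self.hue_value}")
        if not 0.0 < self.hue_width <= 1.0:
            raise ValueError(f"hue_width must be in (0, 1], got {self.hue_width}")
        if not 0.0 <= self.saturation_threshold <= 1.0:
            raise ValueError(
                f"saturation_threshold must be in [0, 1], got {self.saturation_threshold}"
            )
        if not 0.0 <= self.isp_low <= self.isp_high <= self.ip_high <= self.iwp_high <= 255.0:
            raise ValueError(
                "intensity cut points must satisfy "
                "0 <= isp_low <= isp_high <= ip_high <= iwp_high <= 255, got "
                f"{self.isp_low}, {self.isp_high}, {self.ip_high}, {self.iwp_high}"
            )
        if self.inp_high != -1.0 and not 0.0 <= self.inp_high <= 255.0:
            raise ValueError(f"inp_high must be -1 or in [0, 255], got {self.inp_high}")

    @property
    def effective_inp_high(self) -> float:
        """Negative-pixel intensity ceiling; the -1 sentinel resolves to iwp_high."""
        return self.iwp_high if self.inp_high == -1.0 else self.inp_high

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def default_params() -> PixelClassParams:
    """The shipped default DAB threshold set (read from the packaged config)."""
    text = resources.files("ppcount.data").joinpath("default_params.json").read_text()
    return PixelClassParams(**json.loads(text))


def load_params(path: str | Path) -> PixelClassParams:
    """Read a flat key/value parameter file (JSON, or INI with a [params] or
    default section) holding exactly the eight threshold keys."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
    else:
        cp = configparser.ConfigParser()
        cp.read(path)
        section = "params" if cp.has_section("params") else cp.default_section
        raw = dict(cp.items(section))
    unknown = set(raw) - set(_PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter keys in {path}: {sorted(unknown)}")
    return PixelClassParams(**{k: float(v) for k, v in raw.items()})
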