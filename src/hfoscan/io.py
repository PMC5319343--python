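"""Raw-recording container and flat int16 binary file I/O.

Recordings are stored the way long-term rodent EEG acquisition systems
write them: one flat binary file of little-endian signed 16-bit integers
per channel per recording block, named ``rat{R}_ch{CC}_file{FFF}.bin``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ADC_MIN = -(2**15)
ADC_MAX = 2**15 - 1

_FILENAME_RE = re.compile(r"rat(\d+)_ch(\d+)_file(\d+)\.bin$")


@dataclass
class RawRecording:
    """A single-channel EEG block of signed 16-bit ADC counts.

    Parameters
    ----------
    samples : ndarray of int16
        Raw ADC counts ``d_i``.
    sampling_rate : float
        Samples per second (the rat database runs at ~12207 Hz).
    rat_id, channel_id, file_no : int
        Identity of the block within the database layout.
    meta : dict
        Free-form annotations; the synthetic generator records ground-truth
        events, corruption spans and clipping counts here.
    """

    samples: np.ndarray
    sampling_rate: float = 12207.0
    rat_id: int = 1
    channel_id: int = 1
    file_no: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.int16)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def L(self) -> int:
        """Number of samples in the file."""
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.L / self.sampling_rate

    @property
    def filename(self) -> str:
        return f"rat{self.rat_id:03d}_ch{self.channel_id:02d}_file{self.file_no:03d}.bin"

    def astype_float(self) -> np.ndarray:
        return self.samples.astype(np.float64)


def write_bin(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording as flat little-endian int16 binary."""
    path = Path(path)
    rec.samples.astype("<i2").tofile(path)
    return path


def read_bin(
    path: str | Path,
    sampling_rate: float = 12207.0,
    rat_id: int | None = None,
    channel_id: int | None = None,
    file_no: int | None = None,
) -> RawRecording:
    """Read a flat little-endian int16 binary file.

    Identity fields are parsed from the ``rat{R}_ch{CC}_file{FFF}.bin``
    name when not given explicitly.
    """
    path = Path(path)
    samples = np.fromfile(path, dtype="<i2")
    m = _FILENAME_RE.search(path.name)
    if m is not None:
        r, c, f = (int(g) for g in m.groups())
    else:
        r, c, f = 1, 1, 1
    return RawRecording(
        samples=samples,
        sampling_rate=sampling_rate,
        rat_id=rat_id if rat_id is not None else r,
        channel_id=channel_id if channel_id is not None else c,
        file_no=file_no if file_no is not None else f,
    )


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
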