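"""Multi-lead signal containers and readers/writers.

Two on-disk formats are supported:

* a minimal WFDB subset (``.hea`` header + 16-bit little-endian ``.dat``,
  signal format 16), enough to round-trip records written by this package
  and to read PTB-style headers, and
* a delimited text table (tab or comma), one header line of lead names and
  one row per sample, preceded by a ``#`` metadata line carrying the record
  id and sampling rate.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiLeadRecord",
    "read_wfdb",
    "write_wfdb",
    "read_delimited",
    "write_delimited",
]


@dataclass
class MultiLeadRecord:
    """Named, equal-length, real-valued lead signals at a common sampling rate.

    Lead lookup is case-insensitive; the stored order is preserved.
    Amplitudes are in ``units`` (millivolts unless a source header says
    otherwise).
    """

    record_id: str
    sampling_rate: float
    leads: dict[str, np.ndarray] = field(default_factory=dict)
    units: str = "mV"

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if not self.leads:
            raise ValueError("a record needs at least one lead")
        self.leads = {name: np.asarray(sig, dtype=float) for name, sig in self.leads.items()}
        lengths = {name: sig.shape for name, sig in self.leads.items()}
        shapes = set(lengths.values())
        if len(shapes) != 1 or any(len(s) != 1 for s in shapes):
            raise ValueError(f"all leads must be equal-length 1-D arrays, got {lengths}")

    @property
    def lead_names(self) -> list[str]:
        return list(self.leads)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.leads.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def _resolve(self, name: str) -> str:
        lowered = {k.lower(): k for k in self.leads}
        try:
            return lowered[name.lower()]
        except KeyError:
            raise KeyError(
                f"record {self.record_id!r} has no lead {name!r}; "
                f"available leads: {', '.join(self.leads)}"
            ) from None

    def lead(self, name: str) -> np.ndarray:
        """Return one lead by (case-insensitive) name."""
        return self.leads[self._resolve(name)]

    def select(self, names: list[str]) -> "MultiLeadRecord":
        """Return a sub-record with the requested leads, in the requested order."""
        return MultiLeadRecord(
            record_id=self.record_id,
            sampling_rate=self.sampling_rate,
            leads={self._resolve(n): self.lead(n) for n in names},
            units=self.units,
        )

    def with_leads(self, leads: dict[str, np.ndarray]) -> "MultiLeadRecord":
        """Copy of this record with the signals replaced."""
        return MultiLeadRecord(self.record_id, self.sampling_rate, leads, self.units)

    def as_array(self) -> np.ndarray:
        """Stack leads into an ``(n_samples, n_leads)`` array (stored order)."""
        return np.column_stack([self.leads[n] for n in self.leads])


# ---------------------------------------------------------------------------
# WFDB subset (format 16)
# ---------------------------------------------------------------------------

_DEFAULT_GAIN = 2000.0  # ADC units per mV -> 0.5 uV quantization


def write_wfdb(record: MultiLeadRecord, directory: str, gain: float = _DEFAULT_GAIN) -> str:
    """Write ``record`` as ``<record_id>.hea`` / ``<record_id>.dat`` (format 16).

    Returns the path of the header file. Samples are quantized to
    ``round(value * gain)`` 16-bit integers; values outside the int16 range
    raise rather than wrap.
    """
    os.makedirs(directory, exist_ok=True)
    name = record.record_id
    dat_name = f"{name}.dat"
    signals = record.as_array()
    raw = np.round(signals * gain)
    if np.any(np.abs(raw) > 32767):
        raise ValueError("signal exceeds int16 range at the chosen gain")
    raw = raw.astype("<i2")

    hea_path = os.path.join(directory, f"{name}.hea")
    fs = record.sampling_rate
    fs_str = f"{fs:g}"
    with open(hea_path, "w") as f:
        f.write(f"{name} {len(record.leads)} {fs_str} {record.n_samples}\n")
        for j, lead in enumerate(record.leads):
            first = int(raw[0, j])
            checksum = int(np.sum(raw[:, j], dtype=np.int64) % 65536)
            f.write(
                f"{dat_name} 16 {gain:g}(0)/{record.units} 16 0 {first} {checksum} 0 {lead}\n"
            )
    with open(os.path.join(directory, dat_name), "wb") as f:
        raw.reshape(-1).tofile(f)
    return hea_path


def _parse_gain(token: str) -> tuple[float, float, str]:
    """Parse a WFDB gain token like ``2000``, ``2000(0)/mV`` -> (gain, baseline, units)."""
    units = "mV"
    if "/" in token:
        token, units = token.split("/", 1)
    baseline = 0.0
    m = re.match(r"^([-+0-9.eE]+)(?:\(([-+0-9.eE]+)\))?$", token)
    if not m:
        raise ValueError(f"cannot parse WFDB gain specification {token!r}")
    gain = float(m.group(1))
    if m.group(2) is not None:
        baseline = float(m.group(2))
    if gain == 0:
        gain = 200.0  # WFDB convention: 0 means the default gain
    return gain, baseline, units


def read_wfdb(path: str, lead_names: list[str] | None = None) -> MultiLeadRecord:
    """Read a WFDB record (format 16, single ``.dat`` file).

    ``path`` may be the header path or the record path without extension.
    ``lead_names`` selects leads (case-insensitive) in the requested order;
    ``None`` reads all leads.
    """
    hea_path = path if path.endswith(".hea") else path + ".hea"
    if not os.path.exists(hea_path):
        raise FileNotFoundError(f"WFDB header not found: {hea_path}")
    with open(hea_path) as f:
        lines = [ln.strip() for ln in f if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0

    sig_lines = lines[1 : 1 + n_sig]
    if len(sig_lines) != n_sig:
        raise ValueError(f"header {hea_path} declares {n_sig} signals, found {len(sig_lines)}")

    dat_files: list[str] = []
    gains, baselines, units_list, descs = [], [], [], []
    for k, ln in enumerate(sig_lines):
        tok = ln.split()
        dat_files.append(tok[0])
        if tok[1].split("x")[0] != "16":
            raise ValueError(f"unsupported WFDB signal format {tok[1]!r} (only 16)")
        gain, baseline, units = _parse_gain(tok[2]) if len(tok) > 2 else (200.0, 0.0, "mV")
        gains.append(gain)
        baselines.append(baseline)
        units_list.append(units)
        descs.append(" ".join(tok[8:]) if len(tok) > 8 else f"sig{k}")
    if len(set(dat_files)) != 1:
        raise ValueError("multi-file WFDB records are not supported")

    dat_path = os.path.join(os.path.dirname(hea_path), dat_files[0])
    if not os.path.exists(dat_path):
        raise FileNotFoundError(f"WFDB signal file not found: {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    if n_samp and raw.size != n_samp * n_sig:
        raise ValueError(
            f"{dat_path}: expected {n_samp * n_sig} samples ({n_samp} x {n_sig}), got {raw.size}"
        )
    if raw.size % n_sig:
        raise ValueError(f"{dat_path}: sample count {raw.size} not divisible by {n_sig} signals")
    raw = raw.reshape(-1, n_sig).astype(float)

    leads = {
        descs[j]: (raw[:, j] - baselines[j]) / gains[j] for j in range(n_sig)
    }
    record = MultiLeadRecord(name, fs, leads, units=units_list[0])
    if lead_names is not None:
        record = record.select(lead_names)
    return record


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------

_META_RE = re.compile(r"#\s*record_id=(\S+)\s+sampling_rate=(\S+)")


def write_delimited(record: MultiLeadRecord, path: str, delimiter: str = "\t") -> None:
    """Write a record as delimited text (lead-name header, one row per sample)."""
    with open(path, "w") as f:
        f.write(f"# record_id={record.record_id} sampling_rate={record.sampling_rate!r}\n")
        f.write(delimiter.join(record.leads) + "\n")
        data = record.as_array()
        for row in data:
            f.write(delimiter.join(f"{v:.12g}" for v in row) + "\n")


def read_delimited(path: str, sampling_rate: float | None = None) -> MultiLeadRecord:
    """Read a delimited-text record; delimiter (tab/comma) is auto-detected.

    The sampling rate is taken from the ``#`` metadata line if present,
    otherwise from the ``sampling_rate`` argument.
    """
    with open(path) as f:
        lines = f.read().splitlines()
    record_id = os.path.splitext(os.path.basename(path))[0]
    while lines and lines[0].startswith("#"):
        m = _META_RE.match(lines[0])
        if m:
            record_id = m.group(1)
            sampling_rate = float(m.group(2))
        lines = lines[1:]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty signal file")
    if sampling_rate is None:
        raise ValueError(f"{path}: no sampling-rate metadata; pass sampling_rate explicitly")
    delimiter = "\t" if "\t" in lines[0] else ","
    header = [h.strip() for h in lines[0].split(delimiter)]
    if any(not h for h in header):
        raise ValueError(f"{path}: empty lead name in header")
    columns: list[list[float]] = [[] for _ in header]
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split(delimiter)
        if len(cells) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        for col, cell in zip(columns, cells):
            try:
                col.append(float(cell))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric cell {cell!r}") from None
    if not columns[0]:
        raise ValueError(f"{path}: header but no samples")
    leads = {name: np.array(col) for name, col in zip(header, columns)}
    return MultiLeadRecord(record_id, sampling_rate, leads)
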