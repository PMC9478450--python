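"""Logger-file I/O, configuration and the record-to-results pipeline.

The on-disk logger format is a versioned CSV convention: '#'-prefixed
header lines (format tag, device id, units flag, pulse duration, channel
map) followed by comma-separated rows

    timestamp, cycle_id, phase, ch1, ..., chN

with ISO 8601 UTC timestamps and phase in {baseline, pulse, monitor}.
Phases are stored explicitly so non-default cycle programs parse
unambiguously.  Field loggers corrupt rows (SD-card glitches); corrupted
rows are skipped and counted in a parse report, never silently dropped.

Readings may be stored either as volts (raw divider voltage, converted on
read via the thermistor calibration) or as already-converted degC; the
header's ``units`` flag declares which.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import processing
from .errors import ConfigError, HeatPulseError, ParseError
from .flux import WoodProperties, compute_sap_flow
from .processing import PulseRecord, summarize_pulse
from .thermistor import DividerTopology, ThermistorCal, temperature_to_voltage, voltage_to_temperature
from .velocity import BETA_THRESHOLD, ProbeGeometry, dma_select

__all__ = [
    "FORMAT_TAG",
    "ParseReport",
    "Config",
    "load_config",
    "write_logger_csv",
    "read_logger_csv",
    "process_records",
    "RESULT_COLUMNS",
]

log = logging.getLogger(__name__)

FORMAT_TAG = "js5-logger-format"
FORMAT_VERSION = "1"

RESULT_COLUMNS = [
    "cycle_id",
    "timestamp",
    "depth_cm",
    "beta",
    "method",
    "v_h_cm_hr",
    "v_c_cm_hr",
    "sfd_g_cm2_s",
    "F_g_s",
    "qc_flags",
]

_EPOCH_FMT = "%Y-%m-%dT%H:%M:%S.%f"


def _format_ts(ts: _dt.datetime) -> str:
    return ts.strftime(_EPOCH_FMT)[:-3] + "Z"


def _parse_ts(text: str) -> _dt.datetime:
    return _dt.datetime.strptime(text.rstrip("Z"), _EPOCH_FMT)


@dataclass
class ParseReport:
    """Counts from one logger-file read."""

    n_rows: int = 0
    n_skipped_rows: int = 0
    n_cycles: int = 0
    flagged_cycles: dict[str, list[str]] = field(default_factory=dict)

    def flag(self, cycle_id: str, reason: str):
        self.flagged_cycles.setdefault(cycle_id, []).append(reason)


# ---------------------------------------------------------------------------
# writing

def write_logger_csv(
    records: list[PulseRecord],
    path,
    units: str = "celsius",
    cal: ThermistorCal | None = None,
    device_id: str = "SIM-001",
    start_time: _dt.datetime | None = None,
    cycle_interval: float = 1800.0,
) -> None:
    """Write measurement cycles in the logger CSV convention.

    Wall-clock timestamps are synthesised from ``start_time`` (default
    2021-06-01T00:00:00Z) at one cycle per ``cycle_interval`` seconds, with
    the heat pulse as the cycle's time origin.  With ``units='volts'`` the
    temperatures are converted back through the divider model, emulating a
    logger that stores raw readings.
    """
    if units not in ("celsius", "volts"):
        raise ConfigError(f"units must be 'celsius' or 'volts', got {units!r}")
    if units == "volts":
        cal = cal or ThermistorCal()
    if start_time is None:
        start_time = _dt.datetime(2021, 6, 1, 0, 0, 0)
    if not records:
        raise HeatPulseError("no records to write")

    first = records[0]
    ch_names = list(first.channels)
    t0 = first.t0
    lines = [
        f"# {FORMAT_TAG}: {FORMAT_VERSION}",
        f"# device_id: {device_id}",
        f"# units: {units}",
        f"# t0_s: {t0!r}",
    ]
    for name in ch_names:
        side, depth = first.channel_map[name]
        lines.append(f"# channel: {name},{side},{depth!r}")
    lines.append("timestamp,cycle_id,phase," + ",".join(ch_names))

    for i, rec in enumerate(records):
        pulse_time = start_time + _dt.timedelta(seconds=i * cycle_interval)
        for j, t_rel in enumerate(rec.timestamps):
            if t_rel < 0:
                phase = "baseline"
            elif rec.t0 > 0 and t_rel <= rec.t0:
                phase = "pulse"
            else:
                phase = "monitor"
            ts = pulse_time + _dt.timedelta(seconds=float(t_rel))
            vals = []
            for name in ch_names:
                v = float(rec.channels[name][j])
                if units == "volts":
                    v = float(temperature_to_voltage(v, cal))
                vals.append(repr(v))
            lines.append(
                f"{_format_ts(ts)},{rec.cycle_id},{phase}," + ",".join(vals)
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# reading

def read_logger_csv(
    path, cal: ThermistorCal | None = None
) -> tuple[list[PulseRecord], ParseReport]:
    """Parse a logger CSV into measurement cycles.

    Malformed rows (wrong field count, unparseable numbers or timestamps)
    are skipped and counted.  Cycles whose monitoring phase is shorter than
    the file's typical cycle are flagged "incomplete" but still returned.
    Raises :class:`ParseError` only if the header itself is unreadable.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    header: dict[str, str] = {}
    channel_map: dict[str, tuple[str, float]] = {}
    body_start = None
    columns: list[str] | None = None
    for i, line in enumerate(lines):
        if line.startswith("#"):
            try:
                key, val = line[1:].split(":", 1)
            except ValueError:
                continue
            key, val = key.strip(), val.strip()
            if key == "channel":
                name, side, depth = (p.strip() for p in val.split(","))
                channel_map[name] = (side, float(depth))
            else:
                header[key] = val
        elif line.strip():
            columns = [c.strip() for c in line.split(",")]
            body_start = i + 1
            break
    if body_start is None or columns is None:
        raise ParseError(f"{path}: no column header found")
    if header.get(FORMAT_TAG) != FORMAT_VERSION:
        raise ParseError(
            f"{path}: missing or unsupported '# {FORMAT_TAG}:' header"
        )
    if not channel_map:
        raise ParseError(f"{path}: no '# channel:' declarations in header")
    units = header.get("units", "celsius")
    if units not in ("celsius", "volts"):
        raise ParseError(f"{path}: unknown units {units!r}")
    if units == "volts":
        cal = cal or ThermistorCal()
    t0 = float(header.get("t0_s", 0.0))
    ch_names = columns[3:]

    report = ParseReport()
    # cycle_id -> list of (datetime, phase, [values])
    by_cycle: dict[str, list[tuple[_dt.datetime, str, list[float]]]] = {}
    order: list[str] = []
    for raw in lines[body_start:]:
        if not raw.strip():
            continue
        report.n_rows += 1
        parts = raw.split(",")
        if len(parts) != 3 + len(ch_names):
            report.n_skipped_rows += 1
            continue
        try:
            ts = _parse_ts(parts[0])
            phase = parts[2].strip()
            if phase not in ("baseline", "pulse", "monitor"):
                raise ValueError(phase)
            vals = [float(p) for p in parts[3:]]
        except (ValueError, OverflowError):
            report.n_skipped_rows += 1
            continue
        cid = parts[1].strip()
        if cid not in by_cycle:
            by_cycle[cid] = []
            order.append(cid)
        by_cycle[cid].append((ts, phase, vals))

    records: list[PulseRecord] = []
    monitor_counts = []
    for cid in order:
        rows = sorted(by_cycle[cid], key=lambda r: r[0])
        monitor_counts.append(sum(1 for _, ph, _ in rows if ph == "monitor"))
    modal_monitor = (
        int(np.bincount(monitor_counts).argmax()) if monitor_counts else 0
    )

    for cid, n_monitor in zip(order, monitor_counts):
        rows = sorted(by_cycle[cid], key=lambda r: r[0])
        phases = [ph for _, ph, _ in rows]
        n_base = phases.count("baseline")
        if n_base == 0:
            report.flag(cid, "no-baseline")
            continue
        # phases must appear in baseline -> pulse -> monitor order
        rank = {"baseline": 0, "pulse": 1, "monitor": 2}
        if any(rank[a] > rank[b] for a, b in zip(phases, phases[1:])):
            report.flag(cid, "phase-order")
            continue
        times = [r[0] for r in rows]
        diffs = [
            (b - a).total_seconds() for a, b in zip(times, times[1:])
        ]
        dt = float(np.median(diffs)) if diffs else 0.5
        # pulse fires dt after the last baseline sample
        pulse_start = times[n_base - 1] + _dt.timedelta(seconds=dt)
        t_rel = np.array(
            [(ts - pulse_start).total_seconds() for ts in times]
        )
        values = np.array([r[2] for r in rows], dtype=float)
        if units == "volts":
            values = voltage_to_temperature(values, cal)
        channels = {name: values[:, k] for k, name in enumerate(ch_names)}
        flags = set()
        if n_monitor < modal_monitor:
            flags.add(processing.QC_INCOMPLETE)
            report.flag(cid, "incomplete")
        rec = PulseRecord(
            cycle_id=cid,
            timestamps=t_rel,
            channels=channels,
            t0=t0,
            channel_map=dict(channel_map),
            start_time=_format_ts(pulse_start),
            qc_flags=flags,
        )
        records.append(rec)
    report.n_cycles = len(records)
    return records, report


# ---------------------------------------------------------------------------
# configuration

@dataclass
class Config:
    """Validated processing configuration (see config.example.yaml)."""

    geometry: ProbeGeometry
    wood: WoodProperties
    k: float
    t0: float | None  # None: take the pulse duration from the file header
    hrm_window: tuple[float, float] = (60.0, 100.0)
    dt_floor: float = processing.DEFAULT_DT_FLOOR
    smooth_window: int = processing.DEFAULT_SMOOTH_WINDOW
    baseline_sd_qc: float = processing.DEFAULT_BASELINE_SD_QC
    shared_method: bool = False
    missing_policy: str = "error"
    thermistor: ThermistorCal = field(default_factory=ThermistorCal)


def _require(block: dict, block_name: str, key: str):
    if key not in block:
        raise ConfigError(f"config missing required key '{block_name}.{key}'")
    return block[key]


def load_config(path) -> Config:
    """Load and validate the YAML processing configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}

    geo = raw.get("geometry")
    if geo is None:
        raise ConfigError("config missing required block 'geometry'")
    depths = tuple(float(d) for d in _require(geo, "geometry", "depths"))
    geometry = ProbeGeometry(
        x_d=float(_require(geo, "geometry", "x_d")),
        x_u=float(_require(geo, "geometry", "x_u")),
        depths=depths,
    ).with_annuli(
        sapwood_radius=float(_require(geo, "geometry", "sapwood_radius")),
        heartwood_radius=float(geo.get("heartwood_radius", 0.0)),
    )

    wood_raw = raw.get("wood")
    if wood_raw is None:
        raise ConfigError("config missing required block 'wood'")
    wood = WoodProperties(
        rho_b=float(_require(wood_raw, "wood", "rho_b")),
        m_c=float(_require(wood_raw, "wood", "m_c")),
        c_dw=float(_require(wood_raw, "wood", "c_dw")),
        c_s=float(wood_raw.get("c_s", 4.186)),
        rho_s=float(wood_raw.get("rho_s", 1.0)),
        wound_B=float(wood_raw.get("wound_B", 1.0)),
    )

    med = raw.get("medium")
    if med is None:
        raise ConfigError("config missing required block 'medium'")
    k = float(_require(med, "medium", "k"))
    t0 = med.get("t0")
    t0 = None if t0 is None else float(t0)

    proc = raw.get("processing", {}) or {}
    window = proc.get("hrm_window", (60.0, 100.0))
    if len(window) != 2 or not window[0] < window[1]:
        raise ConfigError("processing.hrm_window must be [start_s, end_s]")

    therm_raw = raw.get("thermistor", {}) or {}
    therm_kwargs = {}
    for yaml_key, attr in (
        ("sh_a", "sh_a"),
        ("sh_b", "sh_b"),
        ("sh_c", "sh_c"),
        ("r_fixed", "r_fixed"),
        ("v_ref", "v_ref"),
    ):
        if yaml_key in therm_raw:
            therm_kwargs[attr] = float(therm_raw[yaml_key])
    if "divider_topology" in therm_raw:
        therm_kwargs["topology"] = DividerTopology(therm_raw["divider_topology"])
    thermistor = ThermistorCal(**therm_kwargs)

    return Config(
        geometry=geometry,
        wood=wood,
        k=k,
        t0=t0,
        hrm_window=(float(window[0]), float(window[1])),
        dt_floor=float(proc.get("dt_floor", processing.DEFAULT_DT_FLOOR)),
        smooth_window=int(proc.get("smooth_window", processing.DEFAULT_SMOOTH_WINDOW)),
        baseline_sd_qc=float(
            proc.get("baseline_sd_qc", processing.DEFAULT_BASELINE_SD_QC)
        ),
        shared_method=bool(proc.get("shared_method", False)),
        missing_policy=str(proc.get("missing_policy", "error")),
        thermistor=thermistor,
    )


# ---------------------------------------------------------------------------
# pipeline

def process_records(
    records: list[PulseRecord], config: Config
) -> pd.DataFrame:
    """Run the full estimator chain over parsed cycles.

    Returns one row per cycle x depth with the velocity, method, flux and
    whole-tree flow columns.  With ``shared_method`` enabled, the mean
    Peclet number across depths decides HRM vs Tmax for every depth of the
    cycle (instead of each depth deciding for itself).
    """
    rows = []
    for rec in records:
        t0 = rec.t0 if config.t0 is None else config.t0
        try:
            summaries = summarize_pulse(
                rec,
                window=config.hrm_window,
                floor=config.dt_floor,
                smooth_window=config.smooth_window,
                baseline_sd_threshold=config.baseline_sd_qc,
            )
        except HeatPulseError as exc:
            log.warning("cycle %s unprocessable: %s", rec.cycle_id, exc)
            continue

        if config.shared_method:
            betas = [s.beta for s in summaries if s.beta is not None]
            if betas:
                shared_beta = float(np.mean(betas))
                for s in summaries:
                    s.beta = shared_beta

        estimates = []
        for s in summaries:
            try:
                estimates.append(
                    dma_select(
                        s, config.geometry, config.k, t0,
                        hrm_window=config.hrm_window,
                    )
                )
            except HeatPulseError as exc:
                log.warning(
                    "cycle %s depth %.2g cm: %s", rec.cycle_id, s.depth, exc
                )

        if not estimates:
            continue
        try:
            result = compute_sap_flow(
                estimates, config.geometry, config.wood,
                missing=config.missing_policy,
            )
            F = result.F
        except HeatPulseError as exc:
            log.warning("cycle %s flux integration: %s", rec.cycle_id, exc)
            F = np.nan
            result = None

        for est in estimates:
            i_depth = list(config.geometry.depths).index(est.depth)
            v_c = (
                result.v_c[i_depth]
                if result is not None
                else est.v_h * config.wood.wound_B
            )
            sfd = result.sfd[i_depth] if result is not None else np.nan
            rows.append(
                {
                    "cycle_id": rec.cycle_id,
                    "timestamp": rec.start_time or "",
                    "depth_cm": est.depth,
                    "beta": est.beta,
                    "method": est.method_selected,
                    "v_h_cm_hr": est.v_h,
                    "v_c_cm_hr": v_c,
                    "sfd_g_cm2_s": sfd,
                    "F_g_s": F,
                    "qc_flags": ";".join(sorted(est.qc_flags)),
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
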