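"""Scan geometry of a MEMS-scanned OR-PAM system.

The geometry couples the lateral raster (fast/slow mirror axes, micrometre
step sizes) to the acoustic axis (sound speed, sampling rate, unfocused
sensor position).  Axis convention used throughout the package:

* volumes are indexed ``(fast, slow, time)``;
* 2-D lateral images are ``(row = slow, col = fast)``;
* all pixel/voxel coordinates are 0-based.

Depth is mapped from the time axis by one-way propagation, ``z_k = k * c /
f_s`` (the laser fires at t = 0 inside the tissue, so a sample records
pressure that travelled ``c * t``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


@dataclass
class ScanGeometry:
    """Physical configuration of the scanner and detector.

    Parameters
    ----------
    step_fast_um, step_slow_um:
        MEMS step sizes along the fast/slow axes (default 4 and 6 um).
    scan_area_mm:
        Lateral extent ``(fast, slow)`` in millimetres (default 1.20 x 0.80).
    sensor_center_mm:
        Position of the unfocused sensor in the volume frame
        ``(x_fast, y_slow, z_depth)`` in mm.  By default the sensor is placed
        obliquely at ``sensor_distance_mm`` from the centre of the scan area,
        45 degrees off the depth axis in the fast/depth plane, so that the
        wave-vector angle to the fast axis is well defined everywhere.
    sensor_radius_mm:
        Radius of the (disk-shaped) sensing surface, default 3.50 mm.
    sensor_distance_mm:
        Stand-off between sensor and object, default 8.80 mm.
    sound_speed_m_s:
        Acoustic speed, default 1540 m/s (soft tissue).
    sample_rate_hz:
        A-line digitisation rate, default 50 MHz.
    pulse_rate_hz:
        Laser pulse repetition rate, default 10 kHz.
    """

    step_fast_um: float = 4.0
    step_slow_um: float = 6.0
    scan_area_mm: tuple[float, float] = (1.20, 0.80)
    sensor_center_mm: tuple[float, float, float] | None = None
    sensor_radius_mm: float = 3.50
    sensor_distance_mm: float = 8.80
    sound_speed_m_s: float = 1540.0
    sample_rate_hz: float = 50e6
    pulse_rate_hz: float = 10e3

    def __post_init__(self) -> None:
        for name in (
            "step_fast_um",
            "step_slow_um",
            "sensor_radius_mm",
            "sensor_distance_mm",
            "sound_speed_m_s",
            "sample_rate_hz",
            "pulse_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if any(a <= 0 for a in self.scan_area_mm):
            raise ValueError(f"scan_area_mm must be positive, got {self.scan_area_mm}")
        if self.sensor_center_mm is None:
            cx = self.scan_area_mm[0] / 2.0
            cy = self.scan_area_mm[1] / 2.0
            d = self.sensor_distance_mm
            self.sensor_center_mm = (
                cx + d * math.sin(math.pi / 4.0),
                cy,
                -d * math.cos(math.pi / 4.0),
            )

    @property
    def axial_step_mm(self) -> float:
        """Depth increment per time sample (one-way), in mm."""
        return self.sound_speed_m_s / self.sample_rate_hz * 1e3

    def voxel_position_mm(self, i, j, k):
        """Physical position of voxel ``(i=fast, j=slow, k=time)`` in mm."""
        return (
            i * self.step_fast_um * 1e-3,
            j * self.step_slow_um * 1e-3,
            k * self.axial_step_mm,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        d = dict(d)
        for key in ("scan_area_mm", "sensor_center_mm"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)
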