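"""Survey-design bookkeeping: grid geometry, retrieval rate, exposure duration."""

from __future__ import annotations

import datetime as _dt

__all__ = ["grid_cell_count", "retrieval_rate", "exposure_duration_days"]


def grid_cell_count(grid_width_m: float, grid_height_m: float,
                    cell_width_m: float, cell_height_m: float) -> int:
    """Number of cells in a rectangular sampling grid.

    Cell dimensions must tile the grid extent to within 1% per axis.
    """
    nx = grid_width_m / cell_width_m
    ny = grid_height_m / cell_height_m
    if abs(nx - round(nx)) > 0.01 * round(nx) or abs(ny - round(ny)) > 0.01 * round(ny):
        raise ValueError(f"cells do not tile the grid: {nx:.3f} × {ny:.3f}")
    return int(round(nx)) * int(round(ny))


def retrieval_rate(n_retrieved: int, n_deployed: int) -> float:
    """Percentage of deployed biomonitors recovered after exposure."""
    if n_deployed <= 0 or n_retrieved < 0 or n_retrieved > n_deployed:
        raise ValueError("need 0 <= n_retrieved <= n_deployed with n_deployed > 0")
    return 100.0 * n_retrieved / n_deployed


def _as_date(d: "_dt.date | str") -> _dt.date:
    return _dt.date.fromisoformat(d) if isinstance(d, str) else d


def exposure_duration_days(start: "_dt.date | str", end: "_dt.date | str",
                           inclusive: bool = True) -> int:
    """Exposure period length in days.

    ``inclusive`` counts both the deployment and the collection day, the usual
    field-report convention.
    """
    start, end = _as_date(start), _as_date(end)
    if end < start:
        raise ValueError("end date before start date")
    return (end - start).days + (1 if inclusive else 0)
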