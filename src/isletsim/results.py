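"""Simulation output container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimulationResult"]


@dataclass
class SimulationResult:
    """Uniformly sampled time series produced by a simulation run.

    Attributes
    ----------
    time : sample times, min (protocol time; burn-in excluded).
    glycemia : sensed glucose concentration, mM.
    insulin : serum insulin (pM in vivo; pmol/kgBW compartment mass in vitro).
    isr : insulin secretion rate binned per sampling interval, pmol/kgBW/min.
    firings : number of unit firing events per sampling interval.
    extras : run metadata and auxiliary series (mass ledger, imposed
        inputs, k3 range, seed, ...).
    """

    time: np.ndarray
    glycemia: np.ndarray
    insulin: np.ndarray
    isr: np.ndarray
    firings: np.ndarray
    extras: dict = field(default_factory=dict)

    @property
    def sample_dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time,
                "glycemia_mM": self.glycemia,
                "insulin_pM": self.insulin,
                "ISR_pmol_kg_min": self.isr,
                "firings": self.firings,
            }
        )

    def to_csv(self, path, metadata: dict | None = None) -> None:
        """Tidy CSV with ``# key: value`` header comments for provenance."""
        meta = dict(self.extras.get("config", {}))
        if metadata:
            meta.update(metadata)
        with open(path, "w") as fh:
            for key in sorted(meta):
                fh.write(f"# {key}: {meta[key]}\n")
            self.to_frame().to_csv(fh, index=False)

    def at_times(self, times) -> pd.DataFrame:
        """Series linearly interpolated onto an arbitrary sampling schedule."""
        times = np.asarray(times, dtype=float)
        return pd.DataFrame(
            {
                "time_min": times,
                "glycemia_mM": np.interp(times, self.time, self.glycemia),
                "insulin_pM": np.interp(times, self.time, self.insulin),
            }
        )
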