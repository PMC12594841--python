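"""The regulon container shared by network inference and activity scoring.

A regulon is one transcription factor together with its inferred targets;
each target carries a mode of regulation in [-1, 1] (sign: activation vs
repression, magnitude: confidence in the sign) and a likelihood weight in
(0, 1] used when aggregating target-level evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Regulon:
    tf: str
    targets: list[str]
    modes: np.ndarray  # in [-1, 1]
    likelihoods: np.ndarray  # in (0, 1], normalized to max 1 within the regulon

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=float)
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        if not (len(self.targets) == len(self.modes) == len(self.likelihoods)):
            raise ValueError(f"regulon {self.tf}: ragged targets/modes/likelihoods")
        if len(set(self.targets)) != len(self.targets):
            # collapse duplicate targets: weights add, modes weight-average,
            # then rescale so the largest weight is 1 (weight scale cancels in
            # the enrichment score, so a duplicated target scores like one)
            merged: dict[str, tuple[float, float]] = {}
            for t, m, w in zip(self.targets, self.modes, self.likelihoods):
                if t in merged:
                    m0, w0 = merged[t]
                    merged[t] = ((m0 * w0 + m * w) / (w0 + w), w0 + w)
                else:
                    merged[t] = (m, w)
            self.targets = list(merged)
            self.modes = np.array([m for m, _ in merged.values()])
            self.likelihoods = np.array([w for _, w in merged.values()])
            self.likelihoods = self.likelihoods / self.likelihoods.max()
        if np.any(np.abs(self.modes) > 1):
            raise ValueError(f"regulon {self.tf}: mode outside [-1, 1]")
        if np.any(self.likelihoods <= 0) or np.any(self.likelihoods > 1):
            raise ValueError(f"regulon {self.tf}: likelihood outside (0, 1]")

    @property
    def size(self) -> int:
        return len(self.targets)


RegulonSet = dict[str, Regulon]


def regulon_set_from_table(df: pd.DataFrame) -> RegulonSet:
    out: RegulonSet = {}
    for tf, grp in df.groupby("tf", sort=True):
        out[str(tf)] = Regulon(
            tf=str(tf),
            targets=[str(t) for t in grp["target"]],
            modes=grp["mode"].to_numpy(dtype=float),
            likelihoods=grp["likelihood"].to_numpy(dtype=float),
        )
    return out


def regulon_set_to_table(rs: RegulonSet) -> pd.DataFrame:
    rows = [
        (r.tf, t, m, w)
        for r in rs.values()
        for t, m, w in zip(r.targets, r.modes, r.likelihoods)
    ]
    return pd.DataFrame(rows, columns=["tf", "target", "mode", "likelihood"])
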