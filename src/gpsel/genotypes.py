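"""Genotype container and per-marker allele statistics.

Biallelic markers are dosage-coded 0/1/2 (heterozygote = 1), counting copies
of the alternate allele.  Missing calls use a sentinel (default -1).  All
encoders and relationship matrices downstream consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x markers integer dosage table.

    Parameters
    ----------
    samples : list of str
        Unique sample identifiers, one per row.
    markers : list of str
        Unique marker identifiers, one per column.
    dosages : ndarray of int, shape (n_samples, n_markers)
        Alternate-allele dosages in {0, 1, 2} or ``missing_code``.
    missing_code : int
        Sentinel for absent calls.
    """

    samples: list[str]
    markers: list[str]
    dosages: np.ndarray
    missing_code: int = MISSING

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if not np.issubdtype(self.dosages.dtype, np.integer):
            if not np.all(np.mod(self.dosages[self.dosages != self.missing_code], 1) == 0):
                raise ValueError("dosages must be integer-valued")
            self.dosages = self.dosages.astype(np.int64)
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} rows")
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} marker ids for {m} columns")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.markers)) != m:
            raise ValueError("duplicate marker identifiers")
        obs = self.dosages[self.dosages != self.missing_code]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            bad = np.argwhere(
                (self.dosages != self.missing_code)
                & ((self.dosages < 0) | (self.dosages > 2))
            )[0]
            raise ValueError(
                f"dosage out of range at sample {self.samples[bad[0]]}, "
                f"marker {self.markers[bad[1]]}"
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == self.missing_code

    def impute_mode(self) -> "GenotypeMatrix":
        """Fill missing calls with the per-marker mode of observed dosages.

        Deterministic: ties between dosage classes break toward the lower
        dosage.  Markers with no observed calls are left missing (callers
        must drop or reject them).
        """
        if not self.missing_mask().any():
            return self
        d = self.dosages.copy()
        for j in range(self.n_markers):
            col = d[:, j]
            miss = col == self.missing_code
            if not miss.any():
                continue
            obs = col[~miss]
            if obs.size == 0:
                continue
            counts = np.bincount(obs, minlength=3)
            col[miss] = int(np.argmax(counts))
        return GenotypeMatrix(self.samples, self.markers, d, self.missing_code)

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.markers, self.dosages[idx], self.missing_code
        )

    def subset_markers(self, names: list[str]) -> "GenotypeMatrix":
        pos = {m: j for j, m in enumerate(self.markers)}
        cols = [pos[m] for m in names]
        return GenotypeMatrix(self.samples, list(names), self.dosages[:, cols], self.missing_code)


@dataclass
class MarkerStats:
    """Per-marker allele and genotype frequencies fitted on training samples.

    ``p`` is the alternate-allele frequency, ``maf = min(p, 1-p)``, and
    ``genotype_freqs`` holds (p00, p01, p11) from observed calls.  Markers
    with no observed calls are flagged in ``undefined``.
    """

    markers: list[str]
    p: np.ndarray
    maf: np.ndarray
    genotype_freqs: np.ndarray  # (m, 3) columns p00, p01, p11
    undefined: np.ndarray = field(default=None)  # bool mask

    def __post_init__(self) -> None:
        if self.undefined is None:
            self.undefined = np.zeros(len(self.markers), dtype=bool)


def allele_stats(G: GenotypeMatrix) -> MarkerStats:
    """Compute allele frequency, MAF and genotype frequencies per marker.

    ``p`` is the mean observed dosage / 2.  All-missing markers get NaN
    statistics and are flagged ``undefined``; downstream encoders reject or
    drop them depending on configuration.
    """
    if G.n_samples < 1:
        raise ValueError("need at least one sample")
    d = G.dosages
    obs = d != G.missing_code
    n_obs = obs.sum(axis=0)
    undefined = n_obs == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        do = np.where(obs, d, 0)
        p = do.sum(axis=0) / (2.0 * n_obs)
        freqs = np.stack(
            [((d == g) & obs).sum(axis=0) / n_obs for g in (0, 1, 2)], axis=1
        )
    p[undefined] = np.nan
    freqs[undefined] = np.nan
    maf = np.minimum(p, 1.0 - p)
    return MarkerStats(list(G.markers), p, maf, freqs, undefined)
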