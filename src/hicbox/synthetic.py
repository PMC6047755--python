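"""Synthetic Hi-C contact generator with known ground truth.

Emulates the three canonical phenotypes of a mammalian contact map at a
fixed working resolution r on a single synthetic chromosome:

* power-law distance decay: the expected count of a bin pair at separation
  d bins is proportional to (d*r + d0)^(-alpha);
* loops: focal enrichment around an off-diagonal anchor pair, entering as
  a multiplicative factor 1 + (f_loop - 1) * exp(-dist^2 / (2 sigma^2))
  with sigma = radius / r bins, so the far field is exactly the decay law;
* contact domains: a constant factor f_dom for bin pairs lying entirely
  inside the domain interval (bright squares on the diagonal).

The overall scale C is set so the expected total equals ``n_contacts``;
realized counts are independent Poisson draws per bin pair (upper triangle
only), emitted as individual contact records. The same seed reproduces the
stream byte for byte. Ground truth (the config plus the expected
center/donut enrichment of every loop at the working resolution) is
serialized alongside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genome import ChromosomeTable, n_bins

DEFAULT_CHROM = "chrS"
DEFAULT_LENGTH = 5_000_000
DEFAULT_RESOLUTION = 10_000


@dataclass(frozen=True)
class LoopSpec:
    """One loop: anchor positions (bp), enrichment factor >= 1, radius (bp)."""

    anchor1: int
    anchor2: int
    enrichment: float
    radius: int = 20_000


@dataclass(frozen=True)
class DomainSpec:
    """One contact domain: interval (bp) with internal enrichment >= 1."""

    start: int
    end: int
    enrichment: float


@dataclass(frozen=True)
class SyntheticConfig:
    chrom: str = DEFAULT_CHROM
    chrom_length: int = DEFAULT_LENGTH
    n_contacts: int = 500_000
    alpha: float = 1.0
    d0: int = DEFAULT_RESOLUTION  # decay offset (bp): keeps the diagonal finite
    resolution: int = DEFAULT_RESOLUTION  # working bin size of the generator
    loops: tuple[LoopSpec, ...] = ()
    domains: tuple[DomainSpec, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.chrom_length <= 0 or self.n_contacts <= 0 or self.resolution <= 0:
            raise ConfigError("chrom_length, n_contacts and resolution must be positive")
        if self.alpha <= 0:
            raise ConfigError(f"decay exponent must be > 0, got {self.alpha}")
        if self.d0 <= 0:
            raise ConfigError(f"decay offset must be > 0, got {self.d0}")
        for lp in self.loops:
            if lp.enrichment < 1:
                raise ConfigError(f"loop enrichment must be >= 1, got {lp.enrichment}")
            if lp.radius <= 0:
                raise ConfigError(f"loop radius must be positive, got {lp.radius}")
            for a in (lp.anchor1, lp.anchor2):
                if not (0 <= a < self.chrom_length):
                    raise ConfigError(
                        f"loop anchor {a} outside chromosome (length {self.chrom_length})"
                    )
        for dm in self.domains:
            if dm.enrichment < 1:
                raise ConfigError(f"domain enrichment must be >= 1, got {dm.enrichment}")
            if not (0 <= dm.start < dm.end <= self.chrom_length):
                raise ConfigError(
                    f"domain [{dm.start}, {dm.end}) outside chromosome "
                    f"(length {self.chrom_length})"
                )

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "chrom_length": self.chrom_length,
            "n_contacts": self.n_contacts,
            "alpha": self.alpha,
            "d0": self.d0,
            "resolution": self.resolution,
            "loops": [
                {
                    "anchor1": l.anchor1,
                    "anchor2": l.anchor2,
                    "enrichment": l.enrichment,
                    "radius": l.radius,
                }
                for l in self.loops
            ],
            "domains": [
                {"start": d.start, "end": d.end, "enrichment": d.enrichment}
                for d in self.domains
            ],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticConfig":
        return cls(
            chrom=doc.get("chrom", DEFAULT_CHROM),
            chrom_length=int(doc.get("chrom_length", DEFAULT_LENGTH)),
            n_contacts=int(doc.get("n_contacts", 500_000)),
            alpha=float(doc.get("alpha", 1.0)),
            d0=int(doc.get("d0", DEFAULT_RESOLUTION)),
            resolution=int(doc.get("resolution", DEFAULT_RESOLUTION)),
            loops=tuple(
                LoopSpec(
                    int(l["anchor1"]),
                    int(l["anchor2"]),
                    float(l["enrichment"]),
                    int(l.get("radius", 20_000)),
                )
                for l in doc.get("loops", [])
            ),
            domains=tuple(
                DomainSpec(int(d["start"]), int(d["end"]), float(d["enrichment"]))
                for d in doc.get("domains", [])
            ),
            seed=int(doc.get("seed", 0)),
        )


def _loop_bins(lp: LoopSpec, res: int) -> tuple[int, int]:
    a, b = sorted((lp.anchor1 // res, lp.anchor2 // res))
    return a, b


def _factor_grid(config: SyntheticConfig, iu: np.ndarray, ju: np.ndarray) -> np.ndarray:
    """Unnormalized expected intensity for bin pairs (iu <= ju)."""
    res = config.resolution
    d = (ju - iu).astype(np.float64)
    lam = np.power(d * res + config.d0, -config.alpha)
    for dm in config.domains:
        b0, b1 = dm.start // res, math.ceil(dm.end / res)
        inside = (iu >= b0) & (iu < b1) & (ju >= b0) & (ju < b1)
        lam[inside] *= dm.enrichment
    for lp in config.loops:
        ai, aj = _loop_bins(lp, res)
        sigma = lp.radius / res
        g = np.exp(-(((iu - ai) ** 2 + (ju - aj) ** 2) / (2.0 * sigma**2)))
        lam *= 1.0 + (lp.enrichment - 1.0) * g
    return lam


@dataclass
class SyntheticTruth:
    """Config plus the realized expected loop enrichments at the working
    resolution (center 3x3 over 11x11 donut, on the lambda grid)."""

    config: SyntheticConfig
    total_expected: float
    total_emitted: int
    loop_expected_enrichment: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config.to_dict(),
                "total_expected": self.total_expected,
                "total_emitted": self.total_emitted,
                "loop_expected_enrichment": self.loop_expected_enrichment,
            },
            indent=2,
        )


class SyntheticResult:
    """Realized contact pixels (upper triangle) with ground truth attached."""

    def __init__(self, config, bin_i, bin_j, counts, scale, truth):
        self.config = config
        self.bin_i = bin_i  # nonzero pixels only
        self.bin_j = bin_j
        self.counts = counts
        self.scale = scale  # C: multiply _factor_grid by this for lambda
        self.truth = truth

    @property
    def n_bins(self) -> int:
        return n_bins(self.config.chrom_length, self.config.resolution)

    def chrom_table(self) -> ChromosomeTable:
        return ChromosomeTable([(self.config.chrom, self.config.chrom_length)])

    def total(self) -> int:
        return int(self.counts.sum())

    def counts_matrix(self) -> np.ndarray:
        """Dense symmetric realized matrix at the working resolution."""
        n = self.n_bins
        m = np.zeros((n, n))
        m[self.bin_i, self.bin_j] = self.counts
        off = self.bin_i != self.bin_j
        m[self.bin_j[off], self.bin_i[off]] = self.counts[off]
        return m

    def contacts_dataframe(self) -> pd.DataFrame:
        """Aggregated records (one row per nonzero pixel, 1-based midpoints)."""
        res = self.config.resolution
        L = self.config.chrom_length
        pos1 = np.minimum(self.bin_i * res + res // 2, L)
        pos2 = np.minimum(self.bin_j * res + res // 2, L)
        return pd.DataFrame(
            {
                "chrom1": self.config.chrom,
                "pos1": pos1,
                "chrom2": self.config.chrom,
                "pos2": pos2,
                "count": self.counts.astype(np.float64),
            }
        )

    def iter_records(self):
        """Individual contact lines, one per realized read, in pixel order."""
        res = self.config.resolution
        L = self.config.chrom_length
        chrom = self.config.chrom
        for i, j, c in zip(self.bin_i, self.bin_j, self.counts):
            p1 = min(int(i) * res + res // 2, L)
            p2 = min(int(j) * res + res // 2, L)
            line = f"{chrom}\t{p1}\t{chrom}\t{p2}\n"
            for _ in range(int(c)):
                yield line

    def loops_bedpe(self) -> str:
        """Loop anchors as BEDPE bin rectangles at the working resolution."""
        res = self.config.resolution
        rows = []
        for k, lp in enumerate(self.config.loops):
            ai, aj = _loop_bins(lp, res)
            rows.append(
                f"{self.config.chrom}\t{ai * res}\t{(ai + 1) * res}\t"
                f"{self.config.chrom}\t{aj * res}\t{(aj + 1) * res}\tloop{k}"
            )
        return "\n".join(rows) + ("\n" if rows else "")

    def write(self, prefix: str) -> dict:
        """Write <prefix>.contacts.tsv, <prefix>.chrom.sizes, <prefix>.truth.json."""
        paths = {
            "contacts": f"{prefix}.contacts.tsv",
            "chrom_sizes": f"{prefix}.chrom.sizes",
            "truth": f"{prefix}.truth.json",
        }
        with open(paths["contacts"], "wt", encoding="utf-8") as fh:
            fh.write("# chrom1\tpos1\tchrom2\tpos2 (one line per contact)\n")
            for line in self.iter_records():
                fh.write(line)
        with open(paths["chrom_sizes"], "wt", encoding="utf-8") as fh:
            fh.write(f"{self.config.chrom}\t{self.config.chrom_length}\n")
        with open(paths["truth"], "wt", encoding="utf-8") as fh:
            fh.write(self.truth.to_json() + "\n")
        return paths


def simulate_contacts(config: SyntheticConfig) -> SyntheticResult:
    """Draw a full synthetic contact list; deterministic in ``config.seed``."""
    config.validate()
    n = n_bins(config.chrom_length, config.resolution)
    iu, ju = np.triu_indices(n)
    iu = iu.astype(np.int32)
    ju = ju.astype(np.int32)
    lam = _factor_grid(config, iu, ju)
    scale = config.n_contacts / lam.sum()
    lam *= scale
    rng = np.random.default_rng(config.seed)
    counts = rng.poisson(lam)
    nz = counts > 0

    truth = SyntheticTruth(
        config=config,
        total_expected=float(config.n_contacts),
        total_emitted=int(counts.sum()),
        loop_expected_enrichment=[
            expected_loop_enrichment(config, lp, scale) for lp in config.loops
        ],
    )
    return SyntheticResult(
        config, iu[nz].astype(np.int64), ju[nz].astype(np.int64), counts[nz], scale, truth
    )


def _patch(config, scale, ci, cj, half):
    """Expected-intensity patch of side 2*half+1 centered on (ci, cj)."""
    ii, jj = np.meshgrid(
        np.arange(ci - half, ci + half + 1),
        np.arange(cj - half, cj + half + 1),
        indexing="ij",
    )
    lo, hi = np.minimum(ii, jj), np.maximum(ii, jj)
    return _factor_grid(config, lo.ravel(), hi.ravel()).reshape(ii.shape) * scale


def expected_loop_enrichment(config: SyntheticConfig, loop: LoopSpec, scale: float) -> float:
    """Center(3x3)/donut(11x11 minus center) ratio on the expected grid."""
    ai, aj = _loop_bins(loop, config.resolution)
    patch = _patch(config, scale, ai, aj, 5)
    center = patch[4:7, 4:7]
    donut_sum = patch.sum() - center.sum()
    return float(center.mean() / (donut_sum / (121 - 9)))


def realized_loop_enrichment(result: SyntheticResult, loop: LoopSpec) -> float:
    """Center(3x3)/donut ratio on the realized counts around one loop."""
    ai, aj = _loop_bins(loop, result.config.resolution)
    sel = (np.abs(result.bin_i - ai) <= 5) & (np.abs(result.bin_j - aj) <= 5)
    patch = np.zeros((11, 11))
    patch[result.bin_i[sel] - ai + 5, result.bin_j[sel] - aj + 5] = result.counts[sel]
    center = patch[4:7, 4:7]
    donut_mean = (patch.sum() - center.sum()) / (121 - 9)
    if donut_mean == 0:
        return math.inf
    return float(center.mean() / donut_mean)


def decay_profile(result: SyntheticResult, d_min: int, d_max: int):
    """Mean realized count per bin-pair at each separation in [d_min, d_max]."""
    n = result.n_bins
    sep = result.bin_j - result.bin_i
    sums = np.bincount(sep, weights=result.counts, minlength=n)
    d = np.arange(d_min, d_max + 1)
    return d, sums[d_min : d_max + 1] / (n - d)


def fit_decay_slope(result: SyntheticResult, d_min: int = 10, d_max: int = 100) -> float:
    """Least-squares slope of log(mean count) vs log(separation in bins)."""
    d, mean = decay_profile(result, d_min, d_max)
    keep = mean > 0
    slope, _ = np.polyfit(np.log(d[keep]), np.log(mean[keep]), 1)
    return float(slope)
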