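"""Recording geometry, band definitions and pipeline configuration.

The defaults describe a 15-channel word-repetition ERP session: six word
conditions (new/old crossed with congruous/incongruous plus the pooled
"all" conditions), 72 trials per condition, 4 s epochs sampled at 250 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

#: Scalp sites: midline, lateral frontal, language areas (Broca Bl/Br,
#: Wernicke Wl/Wr, Brodmann 41 L41/R41), temporal and occipital.
CHANNELS: tuple[str, ...] = (
    "Fz", "Pz", "Cz", "F7", "F8", "Bl", "Br", "L41", "R41",
    "Wl", "Wr", "T5", "T6", "O1", "O2",
)

#: Midline sites carrying the largest ERP component amplitudes.
MIDLINE_CHANNELS: tuple[str, ...] = ("Fz", "Pz", "Cz")

#: Word conditions: New/Old All, New/Old Congruous, New/Old Incongruous.
CONDITIONS: tuple[str, ...] = ("NA", "NC", "NI", "OA", "OC", "OI")

#: Passband edges in Hz for the filtered bands; "raw" is the unfiltered epoch.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

BANDS: tuple[str, ...] = ("raw", "delta", "theta", "alpha", "beta", "gamma")

#: Reduced montage used for faster clinical setups.
CHANNELS5: tuple[str, ...] = ("Fz", "Pz", "Cz", "Wl", "Wr")

#: Reduced filter bank.
BANDS3: tuple[str, ...] = ("raw", "delta", "gamma")

#: Names of the 16 per-graph features, in feature-vector order.
SINGLE_CHANNEL_FEATURES: tuple[str, ...] = (
    "AWD",   # average weighted degree (node strength mean)
    "DD",    # degree distribution index (Poisson lambda)
    "NE",    # network entropy of the degree distribution
    "M",     # Louvain modularity Q
    "APL",   # average path length
    "CC",    # mean local clustering coefficient
    "GIC",   # graph index complexity
    "LE",    # local efficiency
    "GE",    # global efficiency
    "SW",    # small-worldness
    "SMaC",  # size of maximum clique
    "CTSP",  # cost of travelling-salesman tour on hop distances
    "GD",    # graph density
    "IN",    # independence number
    "SMiC",  # size of global minimum cut
    "VCN",   # vertex coloring (chromatic) number
)

#: Sentinel channel label under which the cross-channel CCSS feature is keyed.
CCSS_KEY = "ALL"


@dataclass(frozen=True)
class PipelineConfig:
    """Which channels/bands/conditions/trials feed the feature pipeline.

    ``n_trials=None`` uses every trial in the epoch set; an integer keeps
    the first ``n_trials`` per condition (shorter-session emulation).
    """

    channels: tuple[str, ...] = CHANNELS
    bands: tuple[str, ...] = BANDS
    conditions: tuple[str, ...] = CONDITIONS
    n_trials: int | None = None
    block: int = 20                  # samples per 80 ms block at 250 Hz
    crop: tuple[float, float] = (-1.0, 2.0)   # s relative to word onset
    alpha: float = 0.01              # t-test selection threshold
    n_components: int = 11           # PCA dimensionality
    n_subgroups: int = 31            # ensemble trial subgroups
    subgroup_scheme: str = "contiguous"
    scale_features: bool = False     # PCA on correlation instead of covariance

    def __post_init__(self) -> None:
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        unknown = set(self.bands) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown bands: {sorted(unknown)}")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")

    @property
    def n_features(self) -> int:
        """Feature-vector length: ch x band x 16 x cond + band x CCSS x cond."""
        n_ch, n_b, n_c = len(self.channels), len(self.bands), len(self.conditions)
        return n_ch * n_b * len(SINGLE_CHANNEL_FEATURES) * n_c + n_b * n_c

    @classmethod
    def named(cls, name: str) -> "PipelineConfig":
        """Return one of the standard configurations.

        ``full`` (8676 features), ``channels5`` (2916), ``trials30``
        (8676, first 30 trials only) or ``bands3`` (4338).
        """
        if name == "full":
            return cls()
        if name == "channels5":
            return cls(channels=CHANNELS5)
        if name == "trials30":
            return cls(n_trials=30)
        if name == "bands3":
            return cls(bands=BANDS3)
        raise ValueError(f"unknown configuration {name!r}")

    def restrict(self, **kwargs) -> "PipelineConfig":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)
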