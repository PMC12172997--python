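"""Exception hierarchy for regionenrich."""


class RegionEnrichError(Exception):
    """Base class for all regionenrich errors."""


class BedParseError(RegionEnrichError):
    """A BED/GTF line could not be parsed; message names the line number."""


class ValidationError(RegionEnrichError):
    """An interval or configuration violates an invariant."""


class ConfigurationError(RegionEnrichError):
    """Invalid flag/option combination."""


class BackgroundSizeError(RegionEnrichError):
    """Background smaller than the requested sample size."""


class PlacementError(RegionEnrichError):
    """Random placement failed after bounded retries."""


class EmptyTestError(RegionEnrichError):
    """No regions left to test after filtering."""


class DegenerateRankingError(RegionEnrichError):
    """Ranked test undefined (no hits/misses, or all distances zero)."""
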