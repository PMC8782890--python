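"""Exception hierarchy for the iPPG perfusion-mapping pipeline."""


class IppgError(Exception):
    """Base class for all pipeline errors."""


class FormatError(IppgError):
    """An input file violates its declared format."""


class AlignmentError(IppgError):
    """Video and ECG streams cannot be placed on a common time base."""


class TimingError(IppgError):
    """The cardiac timing reference cannot be established."""


class SizeError(IppgError):
    """An image or grid is too small for the requested tiling."""


class FilterError(IppgError):
    """A waveform is unsuitable for the requested filtering."""


class ConsistencyError(IppgError):
    """Two pipeline artifacts that must agree do not."""


class EmptyRegionError(IppgError):
    """A requested aggregation region contains no valid ROI."""


class ConfigError(IppgError):
    """A configuration value is out of its admissible range."""
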