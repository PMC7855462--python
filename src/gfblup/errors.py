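"""Exception hierarchy shared across the package."""


class GfblupError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GfblupError, ValueError):
    """Invalid simulation or model configuration."""


class DomainError(GfblupError, ValueError):
    """Argument outside its mathematical domain (e.g. MAF threshold > 0.5)."""


class ParseError(GfblupError, ValueError):
    """Malformed input file."""


class EmptyPanelError(GfblupError, ValueError):
    """A filter or subset operation left no usable markers/accessions."""


class PartitionError(GfblupError, ValueError):
    """Invalid marker partition (empty feature, feature = all markers, train/test overlap)."""


class OntologyError(GfblupError, ValueError):
    """Ontology graph violates DAG requirements (cycle detected)."""


class NumericalError(GfblupError, RuntimeError):
    """Linear-algebra failure inside the mixed-model solver."""
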