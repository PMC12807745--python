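"""Exception hierarchy shared across the package."""


class OgtreeError(Exception):
    """Base class for all ogtree errors."""


class TaxonomyError(OgtreeError):
    pass


class TaxonomyParseError(TaxonomyError):
    """Malformed taxonomy row; message carries the line number."""


class CycleError(TaxonomyError):
    """Parent-pointer chain does not terminate at the root."""


class UnknownTaxonError(TaxonomyError):
    pass


class NewickParseError(OgtreeError):
    pass


class LeafLabelError(OgtreeError):
    """Leaf name cannot be split into species and protein identifiers."""


class UnknownSpeciesError(OgtreeError):
    """Leaf species missing from the taxonomy table."""


class DegenerateTreeError(OgtreeError):
    """Tree too small for the requested operation."""


class DegenerateNodeError(OgtreeError):
    """A child clade retains no leaves after outlier exclusion."""


class AllLeavesRemovedError(OgtreeError):
    pass


class EmptyAlignmentError(OgtreeError):
    pass


class UnknownLeafError(OgtreeError):
    pass


class MissingTreeError(OgtreeError):
    pass


class AllLineagesLostError(OgtreeError):
    """Every simulated gene lineage went extinct; retry with a new seed."""


class ConfigError(OgtreeError):
    pass
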