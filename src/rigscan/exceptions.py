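"""Exception hierarchy for rigscan."""


class RigscanError(Exception):
    """Base class for all rigscan errors."""


class InvalidGenotypeError(RigscanError):
    """A genotype code outside {0, 1, 2} (or the missing sentinel) was seen."""


class EmptyDataError(RigscanError):
    """No usable samples remain after complete-case filtering."""


class SingleClassError(RigscanError):
    """Phenotype has a single class, so H(Y) = 0 and RIG is undefined."""


class DegenerateDistributionError(RigscanError):
    """An all-zero count vector has no entropy."""


class CombinationLimitError(RigscanError):
    """The requested exhaustive scan exceeds the configured safety limit."""


class DegenerateNullError(RigscanError):
    """The permutation null has zero spread; standardization is impossible."""


class OrderMismatchError(RigscanError):
    """A null distribution was paired with results of a different order."""


class InfeasibleModelError(RigscanError):
    """No baseline odds in the bracket satisfies the prevalence constraint."""


class ParseError(RigscanError):
    """A genotype file failed validation; the message names the location."""
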