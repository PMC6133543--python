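"""Exception hierarchy shared across the package."""


class LinkageEvoError(Exception):
    """Base class for all package errors."""


class NonPositiveLength(LinkageEvoError):
    """A link length is zero, negative, or non-finite."""


class NonClosableLinkage(LinkageEvoError):
    """The four links cannot form a closed quadrilateral at the requested angle
    (or at any angle)."""


class RangeOutsideAssembly(NonClosableLinkage):
    """A requested input-rotation range leaves the assembly (closure) range."""


class ParseError(LinkageEvoError):
    """Malformed tree or table input."""


class MissingBranchLength(ParseError):
    """Newick tree with one or more edges lacking a branch length."""


class EmptyOverlap(LinkageEvoError):
    """Tree tips and trait-table species share no labels."""


class LambdaOutOfRange(LinkageEvoError):
    """Pagel's lambda outside [0, 1]."""


class SingularDesign(LinkageEvoError):
    """Rank-deficient predictor matrix in a GLS fit."""


class SingularCovariance(LinkageEvoError):
    """Phylogenetic covariance matrix is not positive definite."""


class ConvergenceFailure(LinkageEvoError):
    """A numerical optimiser failed to locate a maximum."""


class InvalidBurnin(LinkageEvoError):
    """Burn-in fraction outside [0, 1)."""


class InsufficientSamples(LinkageEvoError):
    """Too few post-burn-in MCMC samples for the requested diagnostic."""


class ChainDivergence(LinkageEvoError):
    """Replicate MCMC chains disagree beyond the convergence threshold."""


class RejectionLimitExceeded(LinkageEvoError):
    """Rejection sampling for closable linkages exceeded its failure budget."""
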