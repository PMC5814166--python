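"""Exception hierarchy shared across the package."""


class LifemarketError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(LifemarketError):
    """A valuation or scenario configuration is malformed or violates an invariant."""


class RecordParseError(LifemarketError):
    """A record table could not be parsed; carries the offending row where known."""


class UnregisteredTypeError(LifemarketError):
    """A record references a type key absent from the type registry."""


class EnumerationCapError(LifemarketError):
    """A per-user record set exceeds the exact-enumeration cap."""


class PedigreeError(LifemarketError):
    """Pedigree structure violation: cycles, missing parents, unknown ids."""


class LedgerError(LifemarketError):
    """Chain or Merkle-tree misuse (absent leaf, empty chain, bad batch)."""


class ThresholdError(LifemarketError):
    """Too few Shamir shares, mixed splits, or an inadmissible (N, K) pair."""


class WorkflowError(LifemarketError):
    """A marketplace workflow precondition failed (balances, catalog status)."""
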