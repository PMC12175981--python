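"""Exception hierarchy for volatrank."""


class VolatrankError(Exception):
    """Base class for all volatrank errors."""


class ProfileError(VolatrankError):
    """Malformed or invalid volatile-profile input."""


class TrialError(VolatrankError):
    """Invalid behavioral trial data (choice or trap)."""


class ScreenError(VolatrankError):
    """Invalid input to a correlation/regression screen."""


class FitError(VolatrankError):
    """Degenerate input to a least-squares fit."""


class ConfigError(VolatrankError):
    """Invalid synthetic-data configuration."""
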