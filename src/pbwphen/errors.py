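"""Exception hierarchy shared across the package."""


class PbwphenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PbwphenError, ValueError):
    """Invalid input values (thresholds, temperatures, dates, config)."""


class WeatherGapError(PbwphenError):
    """A weather series has missing days inside the requested interval."""

    def __init__(self, missing_dates):
        self.missing_dates = list(missing_dates)
        preview = ", ".join(str(d.date()) for d in self.missing_dates[:5])
        more = "" if len(self.missing_dates) <= 5 else f" (+{len(self.missing_dates) - 5} more)"
        super().__init__(f"weather series is missing {len(self.missing_dates)} day(s): {preview}{more}")


class RangeCoverageError(PbwphenError):
    """The weather series does not cover the requested date range."""


class TargetUnreachableError(PbwphenError):
    """A degree-day target cannot be reached within the weather series."""

    def __init__(self, target_dd, total_dd, last_date):
        self.target_dd = float(target_dd)
        self.total_dd = float(total_dd)
        self.last_date = last_date
        super().__init__(
            f"target of {target_dd:.2f} DD not reached: series ends {last_date.date()} "
            f"at cumulative {total_dd:.2f} DD"
        )


class InsufficientDataError(PbwphenError):
    """Too few observations for the requested statistic."""


class ConfigurationError(PbwphenError):
    """Invalid run configuration (grids, presets, parameters)."""
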