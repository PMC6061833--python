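"""Exception hierarchy for the morphodyn pipeline.

Every stage raises a subclass of :class:`MorphodynError`; stage errors that
occur mid-movie carry the offending ``frame`` index so long runs can be
resumed after manual correction.
"""


class MorphodynError(Exception):
    """Base class for all morphodyn errors."""


class ParameterError(MorphodynError, ValueError):
    """A parameter is outside its documented domain."""


class ComponentCountError(MorphodynError):
    """A mask did not contain exactly one foreground component."""


class TooSmallComponentError(MorphodynError):
    """A foreground component is degenerate (fewer than 3 boundary pixels)."""


class OutlineInvariantError(MorphodynError):
    """A polygon violates the Outline invariants (simplicity, node count...)."""


class FilterContractError(MorphodynError):
    """A contour filter returned nodes violating the Outline invariants."""

    def __init__(self, filter_name: str, reason: str):
        super().__init__(f"contour filter {filter_name!r} broke its contract: {reason}")
        self.filter_name = filter_name


class SnakeCollapseError(MorphodynError):
    """The active contour collapsed (area below the viability floor)."""

    def __init__(self, frame: int | None = None, partial=None):
        msg = "active contour collapsed"
        if frame is not None:
            msg += f" at frame {frame}"
        super().__init__(msg)
        self.frame = frame
        #: outlines of the frames segmented successfully before the collapse
        self.partial = partial if partial is not None else []


class SeedError(MorphodynError):
    """Seed labels are empty on one side, overlapping, or out of bounds."""


class EmptyOffsetError(MorphodynError):
    """An inward contour offset exceeded the maximal inscribed radius."""


class SchemaError(MorphodynError):
    """A workflow JSON document violates the schema."""

    def __init__(self, json_path: str, reason: str):
        super().__init__(f"schema violation at {json_path}: {reason}")
        self.json_path = json_path
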