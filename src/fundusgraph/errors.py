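"""Failure signals raised by the pipeline stages.

Each corresponds to a per-image condition the cohort runner records and
skips (images are discarded from cohort statistics, never silently dropped).
"""


class FundusGraphError(Exception):
    """Base class for pipeline failures."""


class SegmentationFailure(FundusGraphError):
    """No vessel component of sufficient size could be segmented."""


class DiscNotFound(FundusGraphError):
    """Optic-disc detection confidence fell below threshold."""


class CentralAssignmentError(FundusGraphError):
    """No graph node close enough to the optic disc to act as central node."""


class GraphExtractionError(FundusGraphError):
    """Skeleton without any endpoint or bifurcation (e.g. a pure cycle)."""
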