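"""Exception types shared across the package."""


class NetscaleError(Exception):
    """Base class for all package-specific errors."""


class MeshError(NetscaleError):
    """Invalid triangle mesh (bad indices, degenerate faces...)."""


class UnreachableLandmarkError(NetscaleError):
    """A landmark pair has no path on the surface graph and no finite cap was configured."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(
            f"{len(self.pairs)} landmark pair(s) unreachable on the mesh "
            f"(first: {self.pairs[0]}); configure a finite cap to proceed"
        )


class LandmarkMismatchError(NetscaleError):
    """Landmark id schemas disagree between subjects or between model and subject."""

    def __init__(self, missing_ids, message=None):
        self.missing_ids = sorted(missing_ids)
        super().__init__(
            message or f"landmark ids missing or mismatched: {self.missing_ids}"
        )
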