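"""Exception hierarchy shared across pipeline stages."""


class ScigeoError(Exception):
    """Base class for all package errors."""


class ArticleParseError(ScigeoError):
    """Raised when an article representation cannot be parsed.

    Carries the article_id so corpus runs can report which input failed.
    """

    def __init__(self, article_id: str, message: str):
        self.article_id = article_id
        super().__init__(f"{article_id}: {message}")


class DocumentEmptyError(ArticleParseError):
    """Raised when an article has no usable body content."""


class StageError(ScigeoError):
    """Raised when a processing stage fails on one unit of work.

    Provenance identifies the article/paragraph so the corpus run can skip
    the unit and continue.
    """

    def __init__(self, message: str, provenance=None):
        self.provenance = provenance
        super().__init__(message)


class GazetteerLoadError(ScigeoError):
    """Raised when a gazetteer file yields no valid records."""


class BackendError(ScigeoError):
    """Raised when a geocoding backend fails (after retries)."""

    def __init__(self, query: str, message: str):
        self.query = query
        super().__init__(f"geocoding {query!r}: {message}")


class EvaluationError(ScigeoError):
    """Raised on inconsistent evaluation inputs (missing judgment, unknown article)."""
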