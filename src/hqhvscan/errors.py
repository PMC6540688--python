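"""Exception hierarchy.

Everything raised on bad input data derives from :class:`DataError`, so the
command-line layer can map "your file/arguments are wrong" to exit code 1
while genuine usage errors stay with click's exit code 2.
"""


class DataError(Exception):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line
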