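"""Structured run logging.

Every filtering / pipeline step reports what it did through a :class:`RunLog`,
which mirrors each event to the standard :mod:`logging` machinery (human
readable) and, optionally, to a JSON-lines file (machine readable).  Keeping
this dual trail makes registry analyses auditable: which individuals were
dropped, by which rule, with which parameters.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Optional

_logger = logging.getLogger("pedkin")


class RunLog:
    """Append-only event log (text via ``logging`` + optional JSONL file)."""

    def __init__(self, jsonl_path: Optional[str | Path] = None) -> None:
        self._fh = open(jsonl_path, "a", encoding="utf-8") if jsonl_path else None

    def log(self, event: str, **fields: Any) -> None:
        _logger.info("%s %s", event, fields if fields else "")
        if self._fh is not None:
            self._fh.write(json.dumps({"event": event, **fields}, default=str) + "\n")
            self._fh.flush()

    def warn(self, event: str, **fields: Any) -> None:
        _logger.warning("%s %s", event, fields if fields else "")
        if self._fh is not None:
            self._fh.write(
                json.dumps({"event": event, "level": "warning", **fields}, default=str)
                + "\n"
            )
            self._fh.flush()

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None


_default = RunLog()


def get_runlog() -> RunLog:
    """Module-wide default log (text only, no JSONL sink)."""
    return _default
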