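"""JSON-lines event log for a run.

Every prompt, backend response, generated script, screening decision and
execution result is appended as one JSON object per line, so a recorded
run can be audited or replayed without re-executing anything.
"""

from __future__ import annotations

import json
import os
import time
from pathlib import Path
from typing import Any, Iterator


class RunLog:
    def __init__(self, path: str | os.PathLike):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        # truncate: one log per run
        self.path.write_text("")

    def append(self, event: str, **payload: Any) -> None:
        record = {"ts": time.time(), "event": event, **payload}
        with self.path.open("a") as fh:
            fh.write(json.dumps(record, default=str) + "\n")


class NullLog:
    """Log sink that drops everything (for library use without a workspace)."""

    def append(self, event: str, **payload: Any) -> None:  # noqa: D401
        pass


def read_events(path: str | os.PathLike) -> Iterator[dict]:
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield json.loads(line)
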