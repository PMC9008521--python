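"""Message-stream container and JSON Lines I/O.

A stream is a sequence of :class:`Tweet` records — id, calendar date,
text, language tag and a retweet flag.  On disk a stream is JSON Lines,
one message per line, UTF-8, keys ``{id, date, text, lang, is_retweet}``.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

_REQUIRED_KEYS = ("id", "date", "text", "lang", "is_retweet")


@dataclass(frozen=True, slots=True)
class Tweet:
    """One message: day-precision timestamp, raw text and retweet flag."""

    id: str
    date: dt.date
    text: str
    lang: str
    is_retweet: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "id": self.id,
                "date": self.date.isoformat(),
                "text": self.text,
                "lang": self.lang,
                "is_retweet": self.is_retweet,
            },
            ensure_ascii=False,
            separators=(",", ":"),
        )


def parse_line(line: str) -> Tweet:
    """Parse one JSONL line into a Tweet; raises ValueError on malformed input."""
    obj = json.loads(line)
    missing = [k for k in _REQUIRED_KEYS if k not in obj]
    if missing:
        raise ValueError(f"missing keys: {missing}")
    if not obj["text"]:
        raise ValueError("empty text")
    return Tweet(
        id=str(obj["id"]),
        date=dt.date.fromisoformat(obj["date"]),
        text=obj["text"],
        lang=str(obj["lang"]),
        is_retweet=bool(obj["is_retweet"]),
    )


def write_stream(tweets: Iterable[Tweet], path) -> int:
    """Write tweets as JSON Lines; returns the number of lines written."""
    n = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for tw in tweets:
            fh.write(tw.to_json())
            fh.write("\n")
            n += 1
    return n


def read_stream(
    path, *, max_malformed_fraction: float = 0.01
) -> Iterator[Tweet]:
    """Stream tweets from a JSON Lines file.

    Malformed lines are logged and skipped; if more than
    ``max_malformed_fraction`` of all lines are malformed the reader
    aborts with a ValueError.  A summary count is logged at the end.
    """
    path = Path(path)
    n_ok = 0
    n_bad = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                tweet = parse_line(line)
            except (ValueError, KeyError, json.JSONDecodeError) as exc:
                n_bad += 1
                logger.warning("%s:%d malformed line skipped (%s)", path, lineno, exc)
                total = n_ok + n_bad
                if total >= 100 and n_bad / total > max_malformed_fraction:
                    raise ValueError(
                        f"{path}: {n_bad}/{total} malformed lines exceeds "
                        f"{max_malformed_fraction:.1%} threshold"
                    ) from exc
                continue
            n_ok += 1
            yield tweet
    if n_bad:
        total = n_ok + n_bad
        if n_bad / max(total, 1) > max_malformed_fraction:
            raise ValueError(
                f"{path}: {n_bad}/{total} malformed lines exceeds "
                f"{max_malformed_fraction:.1%} threshold"
            )
        logger.info("%s: parsed %d lines, skipped %d malformed", path, n_ok, n_bad)
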