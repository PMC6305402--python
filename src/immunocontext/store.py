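"""SQLite-backed feature store.

During analysis each slide writes to its own database; the per-slide
databases are merged into a single cohort store at the end, so slide-level
computation parallelizes without write contention.  The schema is plain so
external tools can query it:

* ``feature_values(slide_id, feature, value, reason)`` — ``value`` is NULL
  when unavailable and ``reason`` says why (``region_missing`` or
  ``nonfinite``).
* ``slides(slide_id, content_hash, config_hash, n_objects, computed_at)`` —
  provenance; the (content, config) hash pair keys result-level caching.
"""

from __future__ import annotations

import sqlite3
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

_SCHEMA = """
CREATE TABLE IF NOT EXISTS feature_values (
    slide_id TEXT NOT NULL,
    feature  TEXT NOT NULL,
    value    REAL,
    reason   TEXT NOT NULL DEFAULT 'none',
    PRIMARY KEY (slide_id, feature)
);
CREATE TABLE IF NOT EXISTS slides (
    slide_id     TEXT PRIMARY KEY,
    content_hash TEXT,
    config_hash  TEXT,
    n_objects    INTEGER,
    computed_at  TEXT
);
"""


class FeatureStore:
    """Thin wrapper over one sqlite database of feature values."""

    def __init__(self, path):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.executescript(_SCHEMA)
        self.conn.commit()

    def close(self):
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- writing ------------------------------------------------------------

    def write_slide(self, slide_id, values, content_hash="", config_hash="",
                    n_objects=0) -> None:
        """Replace all stored values of one slide (idempotent)."""
        rows = [(slide_id, fv.feature, fv.value, fv.reason) for fv in values]
        with self.conn:
            self.conn.execute("DELETE FROM feature_values WHERE slide_id = ?", (slide_id,))
            self.conn.executemany(
                "INSERT INTO feature_values VALUES (?, ?, ?, ?)", rows
            )
            self.conn.execute(
                "INSERT OR REPLACE INTO slides VALUES (?, ?, ?, ?, ?)",
                (slide_id, content_hash, config_hash, n_objects,
                 datetime.now(timezone.utc).isoformat()),
            )

    def merge_from(self, other_path) -> None:
        """Copy all slides of another store into this one (replacing)."""
        self.conn.execute("ATTACH DATABASE ? AS src", (str(other_path),))
        try:
            with self.conn:
                self.conn.execute(
                    "DELETE FROM feature_values WHERE slide_id IN (SELECT slide_id FROM src.slides)"
                )
                self.conn.execute(
                    "INSERT INTO feature_values SELECT * FROM src.feature_values"
                )
                self.conn.execute(
                    "INSERT OR REPLACE INTO slides SELECT * FROM src.slides"
                )
        finally:
            self.conn.execute("DETACH DATABASE src")

    # -- reading ------------------------------------------------------------

    def has_slide(self, slide_id, content_hash, config_hash) -> bool:
        cur = self.conn.execute(
            "SELECT 1 FROM slides WHERE slide_id=? AND content_hash=? AND config_hash=?",
            (slide_id, content_hash, config_hash),
        )
        return cur.fetchone() is not None

    def slide_ids(self) -> list:
        return [r[0] for r in self.conn.execute("SELECT slide_id FROM slides ORDER BY slide_id")]

    def load_matrix(self) -> pd.DataFrame:
        """Slides x features DataFrame; unavailable entries are NaN."""
        df = pd.read_sql_query(
            "SELECT slide_id, feature, value FROM feature_values", self.conn
        )
        if df.empty:
            return pd.DataFrame()
        mat = df.pivot(index="slide_id", columns="feature", values="value")
        return mat.sort_index().sort_index(axis=1)

    def content_digest(self) -> str:
        """Hash of all stored values (order-independent); merge-invariance checks."""
        import hashlib

        h = hashlib.sha256()
        for row in self.conn.execute(
            "SELECT slide_id, feature, value, reason FROM feature_values "
            "ORDER BY slide_id, feature"
        ):
            val = "None" if row[2] is None else f"{row[2]:.12e}"
            h.update(f"{row[0]}|{row[1]}|{val}|{row[3]}\n".encode())
        return h.hexdigest()
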