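"""Parallel per-image pipeline execution with SQLite result aggregation.

A *pipeline script* encapsulates the analysis of one image: it is invoked
as ``python script.py <image_path> <result_path>`` and writes one
``trait<TAB>value`` line per measurement to the result path. The runner
parses each filename against a user template, executes the script once per
image in worker subprocesses (no shared mutable state — each image's
results go to its own temporary file), and only after every image has
finished aggregates the temporary files into an SQLite database. Failures
are isolated: a crashing script marks that image failed and the run
continues.

The metadata/feature tables are stored in long format (one row per
image-term and per image-trait), so new camera systems or new traits need
no schema change.
"""

from __future__ import annotations

import datetime
import json
import logging
import os
import sqlite3
import subprocess
import sys
import tempfile
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "VOCABULARY",
    "MetadataTemplate",
    "MetadataMismatch",
    "parse_filename",
    "run_parallel",
    "aggregate_results",
    "export_table",
    "RunSummary",
]

logger = logging.getLogger(__name__)

#: restricted filename-metadata vocabulary; extensible via
#: ``MetadataTemplate(extra_vocabulary=...)`` as community standards evolve.
VOCABULARY = frozenset({
    "plantbarcode", "timestamp", "measurementlabel", "camera", "imgtype",
    "zoom", "lifter", "gain", "exposure", "frame", "id", "other",
})

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


class MetadataMismatch(Exception):
    """Filename does not fit the template; the image is skipped, not fatal."""


@dataclass(frozen=True)
class MetadataTemplate:
    """Positional filename template over the restricted vocabulary.

    ``terms`` maps filename fields (split on ``delimiter``) to metadata
    terms in order; every term must come from the vocabulary and appear at
    most once, except ``other`` which may repeat (captured verbatim).
    """

    terms: tuple[str, ...]
    delimiter: str = "_"
    timestamp_format: str = "%Y-%m-%d"
    extra_vocabulary: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.delimiter:
            raise ValueError("delimiter must be nonempty")
        vocab = VOCABULARY | self.extra_vocabulary
        seen = set()
        for t in self.terms:
            if t not in vocab:
                raise ValueError(f"unknown metadata term {t!r}")
            if t != "other" and t in seen:
                raise ValueError(f"duplicate metadata term {t!r}")
            seen.add(t)

    @classmethod
    def from_string(cls, template: str, delimiter: str = "_",
                    **kwargs) -> "MetadataTemplate":
        return cls(terms=tuple(template.split(delimiter)),
                   delimiter=delimiter, **kwargs)


def parse_filename(filename: str, template: MetadataTemplate) -> dict[str, str]:
    """Positional term -> value mapping from a filename.

    The extension is dropped, the stem split on the template delimiter; a
    field-count mismatch or an unparseable timestamp raises
    :class:`MetadataMismatch` so the runner can skip the file with a
    warning instead of aborting.
    """
    stem = os.path.splitext(os.path.basename(filename))[0]
    fields = stem.split(template.delimiter)
    if len(fields) != len(template.terms):
        raise MetadataMismatch(
            f"{filename!r}: {len(fields)} fields, template expects "
            f"{len(template.terms)}")
    meta: dict[str, str] = {}
    other_n = 0
    for term, value in zip(template.terms, fields):
        if term == "timestamp":
            try:
                dt = datetime.datetime.strptime(value, template.timestamp_format)
            except ValueError as exc:
                raise MetadataMismatch(
                    f"{filename!r}: timestamp {value!r} does not match "
                    f"format {template.timestamp_format!r}") from exc
            meta[term] = dt.isoformat()
        elif term == "other":
            key = "other" if other_n == 0 else f"other{other_n}"
            meta[key] = value
            other_n += 1
        else:
            meta[term] = value
    return meta


@dataclass
class RunSummary:
    processed: int = 0
    skipped: int = 0
    failed: int = 0
    run_id: int | None = None
    failed_images: list[str] = field(default_factory=list)
    skipped_images: list[str] = field(default_factory=list)


def _run_script(script: str, image_path: str, result_path: str) -> bool:
    proc = subprocess.run(
        [sys.executable, script, image_path, result_path],
        capture_output=True, text=True)
    if proc.returncode != 0 or not os.path.exists(result_path):
        logger.warning("pipeline script failed on %s: %s", image_path,
                       proc.stderr.strip()[-500:])
        return False
    return True


def run_parallel(pipeline_script: str, image_dir: str,
                 template: MetadataTemplate, n_workers: int = 1,
                 out_db: str = "results.sqlite") -> RunSummary:
    """Run the pipeline script over every image in *image_dir*.

    Images whose filenames do not fit the template are skipped (with a
    warning); script failures are recorded per image and do not abort the
    run. Aggregation into *out_db* happens strictly after all images have
    finished, from one temporary result file per image, so the database
    content is independent of worker count and completion order.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    files = sorted(
        f for f in os.listdir(image_dir)
        if f.lower().endswith(IMAGE_EXTENSIONS))
    summary = RunSummary()
    jobs: list[tuple[str, dict[str, str]]] = []
    for name in files:
        try:
            meta = parse_filename(name, template)
        except MetadataMismatch as exc:
            logger.warning("skipping %s: %s", name, exc)
            summary.skipped += 1
            summary.skipped_images.append(name)
            continue
        jobs.append((name, meta))

    temp_files: list[str] = []
    with tempfile.TemporaryDirectory(prefix="phenokit_run_") as tmp:
        def _one(job: tuple[str, dict[str, str]]) -> tuple[str, dict, str | None]:
            name, meta = job
            raw = os.path.join(tmp, f"{os.path.splitext(name)[0]}.raw")
            ok = _run_script(pipeline_script, os.path.join(image_dir, name), raw)
            return name, meta, raw if ok else None

        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(_one, jobs))

        for name, meta, raw in sorted(results, key=lambda r: r[0]):
            if raw is None:
                summary.failed += 1
                summary.failed_images.append(name)
                continue
            final = raw.replace(".raw", ".result")
            with open(raw) as src, open(final, "w") as dst:
                dst.write(json.dumps({"image": name, "metadata": meta}) + "\n")
                dst.write(src.read())
            temp_files.append(final)
            summary.processed += 1

        summary.run_id = aggregate_results(
            temp_files, out_db, pipeline=os.path.basename(pipeline_script),
            template=template.delimiter.join(template.terms))
    return summary


_SCHEMA = """
CREATE TABLE IF NOT EXISTS runinfo (
    run_id INTEGER PRIMARY KEY AUTOINCREMENT,
    run_timestamp TEXT NOT NULL,
    pipeline TEXT,
    template TEXT
);
CREATE TABLE IF NOT EXISTS metadata (
    run_id INTEGER NOT NULL,
    image TEXT NOT NULL,
    term TEXT NOT NULL,
    term_order INTEGER NOT NULL,
    value TEXT
);
CREATE TABLE IF NOT EXISTS features (
    run_id INTEGER NOT NULL,
    image TEXT NOT NULL,
    trait TEXT NOT NULL,
    value REAL
);
"""


def _parse_temp_file(path: str) -> tuple[str, dict[str, str], dict[str, float]]:
    with open(path) as fh:
        header = json.loads(fh.readline())
        image, meta = header["image"], header["metadata"]
        feats: dict[str, float] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                trait, value = line.split("\t")
                feats[trait] = float(value)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: expected "
                                 f"'trait<TAB>number', got {line!r}") from exc
    return image, meta, feats


def aggregate_results(temp_files: list[str], out_db: str,
                      pipeline: str = "", template: str = "") -> int:
    """Append one run's temporary result files into the SQLite store.

    Each well-formed temp file contributes one metadata row per template
    term and one features row per measured trait (absent traits simply
    have no row). Malformed files are logged and dropped. Earlier runs in
    the same database are untouched; returns the new run id.
    """
    con = sqlite3.connect(out_db)
    try:
        con.executescript(_SCHEMA)
        cur = con.execute(
            "INSERT INTO runinfo (run_timestamp, pipeline, template) "
            "VALUES (?, ?, ?)",
            (datetime.datetime.now().isoformat(), pipeline, template))
        run_id = cur.lastrowid
        for path in sorted(temp_files):
            try:
                image, meta, feats = _parse_temp_file(path)
            except (ValueError, KeyError, json.JSONDecodeError) as exc:
                logger.warning("dropping malformed result file %s: %s", path, exc)
                continue
            con.executemany(
                "INSERT INTO metadata (run_id, image, term, term_order, value)"
                " VALUES (?, ?, ?, ?, ?)",
                [(run_id, image, term, i, value)
                 for i, (term, value) in enumerate(meta.items())])
            con.executemany(
                "INSERT INTO features (run_id, image, trait, value)"
                " VALUES (?, ?, ?, ?)",
                [(run_id, image, trait, value)
                 for trait, value in sorted(feats.items())])
        con.commit()
        return int(run_id)
    finally:
        con.close()


def export_table(db: str, out: str) -> pd.DataFrame:
    """Export the database as one wide tab-delimited table (R-friendly).

    One row per image (across all runs), metadata columns in template
    order followed by trait columns sorted by name; missing traits are
    empty cells. Re-exporting an unchanged database is byte-identical.
    """
    if not os.path.exists(db):
        raise IOError(f"database not found: {db}")
    con = sqlite3.connect(db)
    try:
        meta = pd.read_sql_query(
            "SELECT run_id, image, term, term_order, value FROM metadata", con)
        feats = pd.read_sql_query(
            "SELECT run_id, image, trait, value FROM features", con)
    finally:
        con.close()

    key = ["run_id", "image"]
    if len(meta):
        term_order = (meta[["term", "term_order"]].drop_duplicates()
                      .sort_values(["term_order", "term"])["term"]
                      .drop_duplicates().tolist())
        wide = meta.pivot_table(index=key, columns="term", values="value",
                                aggfunc="first").reset_index()
        wide = wide[key + [t for t in term_order if t in wide.columns]]
    else:
        wide = pd.DataFrame(columns=key)
    if len(feats):
        fwide = feats.pivot_table(index=key, columns="trait", values="value",
                                  aggfunc="first").reset_index()
        fwide = fwide[key + sorted(c for c in fwide.columns if c not in key)]
        wide = (fwide if wide.empty
                else wide.merge(fwide, on=key, how="outer"))
    wide = wide.sort_values(key).reset_index(drop=True) if len(wide) else wide
    wide.to_csv(out, sep="\t", index=False, na_rep="")
    return wide
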