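"""KEGG REST API access: KGML download, pathway lists, names, id conversion.

All network traffic goes through an injectable :class:`Transport`, so the
whole package is testable (and usable on cached files) without touching
the live API.  The default transport follows KEGG's fair-use guidance:
a configurable inter-request delay (0.34 s, i.e. at most ~3 requests/s)
and three attempts with exponential backoff.

Pathway KGML files are cached on disk as ``<pathway_id>.xml``; a cached
pathway is never re-downloaded.
"""

from __future__ import annotations

import logging
import re
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

DEFAULT_BASE_URL = "https://rest.kegg.jp"
DEFAULT_CACHE_DIR = Path.home() / ".cache" / "keggtopo"

#: supported conversion targets
CONV_TARGETS = ("ncbi-geneid", "uniprot")

_ORG_RE = re.compile(r"^[a-z]{2,4}$")
_PATHWAY_RE = re.compile(r"^[a-z]{2,4}\d{5}$")


class KeggApiError(Exception):
    """A KEGG request failed after all retries."""


class PathwayNotFoundError(KeggApiError):
    """The pathway exists but has no KGML (or does not exist)."""


@dataclass
class ConvMap:
    """KEGG -> external-database identifier mapping (possibly partial)."""

    source_db: str
    target_db: str
    mapping: dict[str, str] = field(default_factory=dict)

    def inverted(self) -> "ConvMap":
        """Target -> KEGG view of the same table (first-listed key wins)."""
        inv: dict[str, str] = {}
        for k, v in self.mapping.items():
            inv.setdefault(v, k)
        return ConvMap(source_db=self.target_db, target_db=self.source_db,
                       mapping=inv)


@dataclass
class NameMap:
    """Accession -> human-readable display name."""

    mapping: dict[str, str] = field(default_factory=dict)

    def get(self, accession: str, default: str = "") -> str:
        return self.mapping.get(accession, default)


class UrllibTransport:
    """Rate-limited stdlib HTTP GET with retries and exponential backoff."""

    def __init__(self, delay: float = 0.34, retries: int = 3,
                 timeout: float = 30.0):
        self.delay = delay
        self.retries = retries
        self.timeout = timeout
        self._last_request = 0.0

    def get(self, url: str) -> str:
        last_exc: Exception | None = None
        for attempt in range(self.retries):
            wait = self._last_request + self.delay - time.monotonic()
            if wait > 0:
                time.sleep(wait)
            self._last_request = time.monotonic()
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return resp.read().decode("utf-8")
            except urllib.error.HTTPError as exc:
                if exc.code == 404:
                    raise PathwayNotFoundError(f"404 for {url}") from exc
                last_exc = exc
            except (urllib.error.URLError, OSError) as exc:
                last_exc = exc
            time.sleep(self.delay * 2 ** attempt)
        raise KeggApiError(f"request failed after {self.retries} attempts: "
                           f"{url} ({last_exc})") from last_exc


class KeggClient:
    """Thin client over the KEGG REST endpoints used by the parser."""

    def __init__(self, transport=None, base_url: str = DEFAULT_BASE_URL,
                 cache_dir: str | Path | None = None):
        self.transport = transport if transport is not None else UrllibTransport()
        self.base_url = base_url.rstrip("/")
        self.cache_dir = Path(cache_dir) if cache_dir else DEFAULT_CACHE_DIR

    # -- pathway listing ---------------------------------------------------

    def list_pathways(self, org_code: str) -> list[str]:
        """Pathway ids (``hsa04014``-style) for one organism."""
        if not _ORG_RE.fullmatch(org_code):
            raise ValueError(f"invalid organism code {org_code!r}")
        body = self.transport.get(f"{self.base_url}/list/pathway/{org_code}")
        ids = []
        for line in body.splitlines():
            if not line.strip():
                continue
            first = line.split("\t")[0].strip()
            ids.append(first.removeprefix("path:"))
        if not ids:
            logger.warning("no pathways listed for organism %r", org_code)
        return ids

    # -- KGML download -----------------------------------------------------

    def fetch_kgml(self, pathway_id: str, cache_dir: str | Path | None = None) -> str:
        """KGML text for one pathway, cached as ``<pathway_id>.xml``."""
        if not _PATHWAY_RE.fullmatch(pathway_id):
            raise ValueError(f"invalid pathway id {pathway_id!r}")
        cache = Path(cache_dir) if cache_dir else self.cache_dir
        cache.mkdir(parents=True, exist_ok=True)
        target = cache / f"{pathway_id}.xml"
        if target.exists():
            return target.read_text(encoding="utf-8")
        text = self.transport.get(f"{self.base_url}/get/{pathway_id}/kgml")
        target.write_text(text, encoding="utf-8")
        return text

    # -- identifier conversion ---------------------------------------------

    def fetch_conv_map(self, source_db: str, target_db: str) -> ConvMap:
        """KEGG ``/conv`` table as a :class:`ConvMap` (KEGG -> target)."""
        if target_db not in CONV_TARGETS:
            raise ValueError(f"target_db must be one of {CONV_TARGETS}, "
                             f"got {target_db!r}")
        body = self.transport.get(f"{self.base_url}/conv/{target_db}/{source_db}")
        mapping: dict[str, str] = {}
        skipped = 0
        for line in body.splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                skipped += 1
                continue
            # first-listed mapping wins for one-to-many results
            mapping.setdefault(parts[0].strip(), parts[1].strip())
        if skipped:
            logger.warning("skipped %d malformed line(s) in conv response",
                           skipped)
        return ConvMap(source_db=source_db, target_db=target_db, mapping=mapping)

    # -- display names -----------------------------------------------------

    _BATCH = 10  # KEGG /list accepts up to 10 '+'-joined accessions

    def fetch_names(self, accessions: list[str]) -> NameMap:
        """Display names via the generic ``/list/<accession>`` endpoint.

        Genes: the description after the first semicolon (the part before
        it is the symbol list).  Compounds and glycans: the first synonym.
        Pathways and anything else: the whole description field.
        Accessions missing from the response are omitted.
        """
        nmap = NameMap()
        todo = [a for a in accessions if a]
        for i in range(0, len(todo), self._BATCH):
            batch = todo[i:i + self._BATCH]
            body = self.transport.get(f"{self.base_url}/list/{'+'.join(batch)}")
            for line in body.splitlines():
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    continue
                acc, desc = parts[0].strip(), parts[-1].strip()
                nmap.mapping[acc] = _parse_name(acc, desc)
        return nmap


def _parse_name(accession: str, description: str) -> str:
    prefix = accession.split(":", 1)[0]
    if prefix in ("cpd", "gl", "dr"):
        return description.split(";", 1)[0].strip()
    if prefix == "path":
        return description
    if ";" in description:
        return description.split(";", 1)[1].strip()
    return description


# -- module-level convenience wrappers (one default client) -----------------

_default_client: KeggClient | None = None


def _client() -> KeggClient:
    global _default_client
    if _default_client is None:
        _default_client = KeggClient()
    return _default_client


def list_pathways(org_code: str) -> list[str]:
    return _client().list_pathways(org_code)


def fetch_kgml(pathway_id: str, cache_dir: str | Path | None = None) -> str:
    return _client().fetch_kgml(pathway_id, cache_dir=cache_dir)


def fetch_conv_map(source_db: str, target_db: str) -> ConvMap:
    return _client().fetch_conv_map(source_db, target_db)


def fetch_names(accessions: list[str]) -> NameMap:
    return _client().fetch_names(accessions)
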