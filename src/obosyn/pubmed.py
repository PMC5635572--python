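"""Optional live PubMed E-utilities adapter for exact-phrase validation.

Network-gated and excluded from the core pipeline/tests: MEDLINE hit
counts drift daily, so results are cached to disk together with the query
date.  Queries use esearch with the phrase quoted and restricted to the
title/abstract field ("..."[TIAB]).

The ``base_url`` is parameterizable so the adapter can be pointed at a
local stub server for offline agreement tests against the local scanner.
"""

from __future__ import annotations

import datetime as _dt
import json
import urllib.parse
import urllib.request
from pathlib import Path

from lxml import etree

__all__ = ["PubMedSearcher", "EUTILS_BASE"]

EUTILS_BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"


class PubMedSearcher:
    """esearch-based exact-phrase counter with an on-disk JSON cache."""

    def __init__(
        self,
        email: str = "",
        cache_dir: str | Path | None = None,
        base_url: str = EUTILS_BASE,
        timeout: float = 30.0,
    ) -> None:
        self.email = email
        self.base_url = base_url.rstrip("/")
        self.timeout = timeout
        self.cache_path: Path | None = None
        self._cache: dict[str, dict] = {}
        if cache_dir is not None:
            Path(cache_dir).mkdir(parents=True, exist_ok=True)
            self.cache_path = Path(cache_dir) / "pubmed_cache.json"
            if self.cache_path.exists():
                self._cache = json.loads(self.cache_path.read_text("utf-8"))

    def _save_cache(self) -> None:
        if self.cache_path is not None:
            self.cache_path.write_text(
                json.dumps(self._cache, indent=0, sort_keys=True), "utf-8"
            )

    def query_term(self, phrase: str) -> str:
        return f'"{phrase}"[TIAB]'

    def count(self, phrase: str) -> int:
        """Number of PubMed documents whose title/abstract contains the
        exact phrase; cached per phrase with the query date."""
        key = phrase.lower()
        if key in self._cache:
            return int(self._cache[key]["count"])
        params = {
            "db": "pubmed",
            "term": self.query_term(phrase),
            "retmax": "0",
        }
        if self.email:
            params["email"] = self.email
        url = f"{self.base_url}/esearch.fcgi?" + urllib.parse.urlencode(params)
        with urllib.request.urlopen(url, timeout=self.timeout) as resp:
            payload = resp.read()
        root = etree.fromstring(payload)
        count = int(root.findtext("Count", default="0"))
        self._cache[key] = {
            "count": count,
            "date": _dt.date.today().isoformat(),
        }
        self._save_cache()
        return count
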