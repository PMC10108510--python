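"""Pluggable block compressors: ZSTD (default), LZMA, GZIP.

Each backend exposes ``compress``/``decompress`` on whole byte blocks.  The
1-byte compressor id stored in the GTB magic code selects the backend on
read.  Two ids are reserved for future extension.
"""

from __future__ import annotations

import lzma
import zlib

import zstandard

from .blocking import BOUND_PRESETS, BoundaryModel

ZSTD_ID, LZMA_ID, GZIP_ID = 0, 1, 2


class Compressor:
    name: str
    id: int

    def __init__(self, level: int = 3):
        self.level = max(0, min(int(level), 7))

    def compress(self, data: bytes) -> bytes:
        raise NotImplementedError

    def decompress(self, data: bytes) -> bytes:
        raise NotImplementedError

    @property
    def bound(self) -> BoundaryModel:
        return BOUND_PRESETS[self.name]


class ZstdCompressor(Compressor):
    name, id = "zstd", ZSTD_ID

    def __init__(self, level: int = 3):
        super().__init__(level)
        # contexts are not shareable across threads: one set per worker
        import threading

        self._local = threading.local()

    def _ctx(self):
        if not hasattr(self._local, "c"):
            self._local.c = zstandard.ZstdCompressor(level=max(self.level, 1))
            self._local.d = zstandard.ZstdDecompressor()
        return self._local

    def compress(self, data: bytes) -> bytes:
        return self._ctx().c.compress(data)

    def decompress(self, data: bytes) -> bytes:
        return self._ctx().d.decompress(data)


class LzmaCompressor(Compressor):
    name, id = "lzma", LZMA_ID

    def compress(self, data: bytes) -> bytes:
        return lzma.compress(data, preset=self.level)

    def decompress(self, data: bytes) -> bytes:
        return lzma.decompress(data)


class GzipCompressor(Compressor):
    name, id = "gzip", GZIP_ID

    def compress(self, data: bytes) -> bytes:
        return zlib.compress(data, level=max(self.level, 1))

    def decompress(self, data: bytes) -> bytes:
        return zlib.decompress(data)


_BY_NAME = {c.name: c for c in (ZstdCompressor, LzmaCompressor, GzipCompressor)}
_BY_ID = {c.id: c for c in (ZstdCompressor, LzmaCompressor, GzipCompressor)}


def get_compressor(name_or_id, level: int = 3) -> Compressor:
    if isinstance(name_or_id, str):
        try:
            cls = _BY_NAME[name_or_id.lower()]
        except KeyError:
            raise ValueError(f"unknown compressor {name_or_id!r}") from None
    else:
        try:
            cls = _BY_ID[int(name_or_id)]
        except KeyError:
            raise ValueError(f"unknown compressor id {name_or_id}") from None
    return cls(level)
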