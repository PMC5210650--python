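"""HTTP surface and command-line interface.

The REST layer is a plain WSGI application (stdlib ``wsgiref`` serves it),
so the wire contract — JSON bodies, a CSV export route, structured 404/422
errors — is framework-neutral and byte-identical to direct query-module
calls on the same store.  The service is read-only.

Endpoints::

    GET /api/search?q=...
    GET /api/autocomplete?q=...
    GET /api/gene/{id}
    GET /api/gene/{id}/variants.csv
    GET /api/transcript/{id}
    GET /api/variant/{chrom-pos-ref-alt}
    GET /api/region/{chrom}-{start}-{stop}
"""

from __future__ import annotations

import json
import re
import sys
from pathlib import Path
from typing import Any, Callable
from urllib.parse import parse_qs

import click

from . import fixtures, query, readviz, store as store_mod
from .ingest import read_carriers
from .model import ModelError, PagePayload

_JSON = "application/json; charset=utf-8"
_CSV = "text/csv; charset=utf-8"


def _json_body(obj: Any, status: str = "200 OK") -> tuple[str, str, bytes]:
    body = obj.to_json() if isinstance(obj, PagePayload) else json.dumps(
        obj, sort_keys=True, separators=(",", ":")
    )
    return status, _JSON, body.encode("utf-8")


def _error(status: str, message: str, **extra: Any) -> tuple[str, str, bytes]:
    payload = {"error": message, "status": int(status.split()[0]), **extra}
    return status, _JSON, json.dumps(payload, sort_keys=True).encode("utf-8")


def create_app(store: store_mod.BrowserStore) -> Callable:
    """Build the WSGI application over a loaded store."""

    routes: list[tuple[re.Pattern, Callable[..., tuple[str, str, bytes]]]] = []

    def route(pattern: str):
        def register(fn):
            routes.append((re.compile(pattern), fn))
            return fn
        return register

    def _q(environ) -> str:
        params = parse_qs(environ.get("QUERY_STRING", ""))
        values = params.get("q", [])
        return values[0] if values else ""

    @route(r"^/api/search$")
    def _search(environ):
        q = _q(environ)
        if not q.strip():
            return _error("400 Bad Request", "missing or empty query parameter q")
        return _json_body(query.resolve_search(q, store).to_dict())

    @route(r"^/api/autocomplete$")
    def _autocomplete(environ):
        q = _q(environ)
        if not q:
            return _error("400 Bad Request", "missing query parameter q")
        return _json_body({"suggestions": query.autocomplete(q, store)})

    @route(r"^/api/gene/(?P<gene_id>[^/]+)/variants\.csv$")
    def _gene_csv(environ, gene_id):
        payload = query.gene_page(gene_id, store)
        if payload.page_kind == "not_found":
            return _error("404 Not Found", f"gene {gene_id!r} not found")
        text = query.export_variant_table_csv(
            payload, populations=store.config.populations
        )
        return "200 OK", _CSV, text.encode("utf-8")

    @route(r"^/api/gene/(?P<gene_id>[^/]+)$")
    def _gene(environ, gene_id):
        payload = query.gene_page(gene_id, store)
        if payload.page_kind == "not_found":
            return _json_body(payload, status="404 Not Found")
        return _json_body(payload)

    @route(r"^/api/transcript/(?P<transcript_id>[^/]+)$")
    def _transcript(environ, transcript_id):
        payload = query.transcript_page(transcript_id, store)
        if payload.page_kind == "not_found":
            return _json_body(payload, status="404 Not Found")
        return _json_body(payload)

    @route(r"^/api/variant/(?P<key>[^/]+)$")
    def _variant(environ, key):
        try:
            payload = query.variant_page(key, store)
        except ModelError as exc:
            return _error("400 Bad Request", str(exc))
        if payload.page_kind == "not_found":
            return _json_body(payload, status="404 Not Found")
        return _json_body(payload)

    @route(r"^/api/region/(?P<chrom>[\w.]+)-(?P<start>\d+)-(?P<stop>\d+)$")
    def _region(environ, chrom, start, stop):
        start_i, stop_i = int(start), int(stop)
        try:
            payload = query.region_page(chrom, start_i, stop_i, store)
        except ValueError as exc:
            return _error("400 Bad Request", str(exc))
        if payload.metadata.get("rejected"):
            return _json_body(payload, status="422 Unprocessable Entity")
        return _json_body(payload)

    def app(environ, start_response):
        path = environ.get("PATH_INFO", "")
        if environ.get("REQUEST_METHOD", "GET") != "GET":
            status, ctype, body = _error("405 Method Not Allowed", "read-only service")
        else:
            for pattern, handler in routes:
                m = pattern.match(path)
                if m:
                    try:
                        status, ctype, body = handler(environ, **m.groupdict())
                    except Exception as exc:  # pragma: no cover - defensive
                        status, ctype, body = _error(
                            "500 Internal Server Error", str(exc)
                        )
                    break
            else:
                status, ctype, body = _error("404 Not Found", f"no route for {path}")
        start_response(status, [
            ("Content-Type", ctype),
            ("Content-Length", str(len(body))),
        ])
        return [body]

    return app


def serve(store_path: str, host: str = "127.0.0.1", port: int = 8000):
    """Load a store and serve it forever over HTTP."""
    from wsgiref.simple_server import make_server

    browser_store = store_mod.load(store_path)  # raises if the path is missing
    app = create_app(browser_store)
    httpd = make_server(host, port, app)
    click.echo(f"serving store {store_path} on http://{host}:{port}", err=True)
    httpd.serve_forever()


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
def main():
    """varbrowse: population variant-frequency browser backend."""


@main.command("simulate")
@click.option("--seed", type=int, required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--genes", "n_genes", type=int, default=4, show_default=True)
@click.option("--variants-per-gene", type=int, default=15, show_default=True)
def cli_simulate(seed, out_dir, n_genes, variants_per_gene):
    """Generate a synthetic input bundle with ground truth."""
    truth = fixtures.generate(
        seed, out_dir, n_genes=n_genes, variants_per_gene=variants_per_gene
    )
    click.echo(f"wrote bundle with {len(truth['variants'])} variants to {out_dir}")


@main.command("build")
@click.option("--vcf", required=True, type=click.Path(exists=True))
@click.option("--gtf", required=True, type=click.Path(exists=True))
@click.option("--coverage", type=click.Path(exists=True))
@click.option("--constraint", type=click.Path(exists=True))
@click.option("--cnv", type=click.Path(exists=True))
@click.option("--dbsnp", type=click.Path(exists=True))
@click.option("--aliases", type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--precompute-threshold", type=int,
              default=store_mod.DEFAULT_PRECOMPUTE_THRESHOLD, show_default=True)
def cli_build(vcf, gtf, coverage, constraint, cnv, dbsnp, aliases, out_dir,
              precompute_threshold):
    """Ingest inputs and write a queryable store."""
    browser_store = store_mod.build(
        vcf, gtf, coverage_path=coverage, constraint_path=constraint,
        cnv_path=cnv, dbsnp_path=dbsnp, alias_path=aliases,
    )
    store_mod.precompute_large_gene_payloads(browser_store, precompute_threshold)
    path = store_mod.save(browser_store, out_dir)
    click.echo(f"wrote {len(browser_store.variants)} variants to {path}")


@main.command("search")
@click.argument("q")
@click.option("--store", "store_dir", required=True, type=click.Path(exists=True))
def cli_search(q, store_dir):
    """Resolve a search query against a built store."""
    browser_store = store_mod.load(store_dir)
    result = query.resolve_search(q, browser_store)
    click.echo(json.dumps(result.to_dict(), sort_keys=True))
    if result.kind == "not_found":
        sys.exit(1)


@main.command("export-csv")
@click.argument("gene")
@click.option("--store", "store_dir", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", type=click.Path())
def cli_export_csv(gene, store_dir, out_path):
    """Export a gene's variant table as CSV (by symbol or gene id)."""
    browser_store = store_mod.load(store_dir)
    model = browser_store.gene_by_id(gene) or browser_store.gene_by_symbol(gene)
    if model is None:
        click.echo(f"gene {gene!r} not found", err=True)
        sys.exit(1)
    payload = query.gene_page(model.gene_id, browser_store)
    text = query.export_variant_table_csv(
        payload, populations=browser_store.config.populations
    )
    if out_path:
        Path(out_path).write_text(text)
    else:
        click.echo(text, nl=False)


@main.command("readviz-manifest")
@click.option("--carriers", required=True, type=click.Path(exists=True))
@click.option("--store", "store_dir", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--window-width", type=int, default=readviz.DEFAULT_WINDOW_WIDTH,
              show_default=True)
@click.option("--batch-size", type=int, default=1000, show_default=True)
def cli_readviz_manifest(carriers, store_dir, out_path, window_width, batch_size):
    """Select carrier samples per variant and write the read-viz manifest."""
    browser_store = store_mod.load(store_dir)
    carrier_map = read_carriers(carriers)
    manifests = []
    for key in sorted(
        carrier_map,
        key=lambda k: (k.split("-")[0], int(k.split("-")[1]), k),
    ):
        variant = browser_store.variant_by_key(key)
        if variant is None:
            click.echo(f"skipping carriers for unknown variant {key}", err=True)
            continue
        selection = readviz.select_samples(carrier_map[key])
        manifests.append(
            readviz.build_manifest(variant, selection, window_width=window_width)
        )
    batches = readviz.batch_manifests(manifests, batch_size)
    n = readviz.write_manifest_tsv(batches, out_path)
    click.echo(f"wrote {n} manifest rows for {len(manifests)} variants to {out_path}")


@main.command("serve")
@click.option("--store", "store_dir", required=True, type=click.Path())
@click.option("--host", default="127.0.0.1", show_default=True)
@click.option("--port", type=int, default=8000, show_default=True)
def cli_serve(store_dir, host, port):
    """Serve a built store over HTTP."""
    try:
        serve(store_dir, host, port)
    except store_mod.StoreError as exc:
        click.echo(str(exc), err=True)
        sys.exit(1)


if __name__ == "__main__":  # pragma: no cover
    main()
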