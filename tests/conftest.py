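import pytest
from hypothesis import settings

from varbrowse import fixtures, store

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

BUNDLE_SEED = 7


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Synthetic input bundle (seed 7) plus its ground-truth dict."""
    out = tmp_path_factory.mktemp("bundle")
    truth = fixtures.generate(BUNDLE_SEED, out)
    return out, truth


@pytest.fixture(scope="session")
def bundle_files(bundle):
    out, _ = bundle
    return fixtures.bundle_paths(out)


@pytest.fixture(scope="session")
def truth(bundle):
    return bundle[1]


@pytest.fixture(scope="session")
def built_store(bundle_files):
    """Store built from the session bundle. Treat as read-only."""
    p = bundle_files
    return store.build(
        p["vcf"], p["gtf"],
        coverage_path=p["coverage"], constraint_path=p["constraint"],
        cnv_path=p["cnv"], dbsnp_path=p["dbsnp"], alias_path=p["aliases"],
    )


def wsgi_get(app, path, query=""):
    """Invoke a WSGI app directly; returns (status, headers, body bytes)."""
    from io import BytesIO

    environ = {
        "REQUEST_METHOD": "GET",
        "PATH_INFO": path,
        "QUERY_STRING": query,
        "SERVER_NAME": "testserver",
        "SERVER_PORT": "80",
        "wsgi.input": BytesIO(b""),
        "wsgi.url_scheme": "http",
    }
    captured = {}

    def start_response(status, headers):
        captured["status"] = status
        captured["headers"] = headers

    body = b"".join(app(environ, start_response))
    return captured["status"], dict(captured["headers"]), body
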