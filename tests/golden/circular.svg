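<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="320.000" height="320.000" viewBox="0 0 320.000 320.000">
  <defs/>
  <rect class="background" x="0.000" y="0.000" width="320.000" height="320.000" fill="#ffffff"/>
  <path id="shade-1" d="M 160.000,10.000 A 150.000,150.000 0 0 1 266.066,53.934 L 160.000,160.000 Z" fill="#cccccc" stroke="none" stroke-width="0" opacity="0.600"/>
  <g id="ring-integrations">
    <path id="integrations-syn7-4-2" d="M 306.014,125.651 A 150.000,150.000 0 0 1 307.829,134.573 L 294.032,136.946 A 136.000,136.000 0 0 0 292.386,128.857 Z" fill="#d95f02" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="integrations-syn7-2-3" d="M 302.935,205.494 A 150.000,150.000 0 0 1 298.687,217.148 L 285.743,211.814 A 136.000,136.000 0 0 0 289.594,201.248 Z" fill="#d95f02" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="integrations-syn7-5-4" d="M 149.091,309.603 A 150.000,150.000 0 0 1 143.071,309.042 L 144.651,295.131 A 136.000,136.000 0 0 0 150.109,295.640 Z" fill="#d95f02" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="integrations-syn7-3-5" d="M 115.889,303.367 A 150.000,150.000 0 0 1 106.247,300.038 L 111.264,286.968 A 136.000,136.000 0 0 0 120.006,289.986 Z" fill="#d95f02" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="integrations-syn7-0-6" d="M 60.054,271.851 A 150.000,150.000 0 0 1 50.325,262.329 L 60.561,252.779 A 136.000,136.000 0 0 0 69.382,261.412 Z" fill="#d95f02" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="integrations-syn7-1-7" d="M 48.547,59.610 A 150.000,150.000 0 0 1 53.632,54.237 L 63.560,64.108 A 136.000,136.000 0 0 0 58.949,68.980 Z" fill="#d95f02" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
  </g>
  <g id="ring-gene-aggregates">
    <path id="gene-aggregates-agg-0-8" d="M 171.590,28.510 A 132.000,132.000 0 0 1 172.205,28.565 L 170.910,42.505 A 118.000,118.000 0 0 0 170.360,42.456 Z" fill="#2b8cbe" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="gene-aggregates-agg-1-9" d="M 212.836,39.036 A 132.000,132.000 0 0 1 223.186,44.105 L 216.484,56.397 A 118.000,118.000 0 0 0 207.232,51.865 Z" fill="#2b8cbe" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="gene-aggregates-agg-2-10" d="M 248.113,61.715 A 132.000,132.000 0 0 1 248.517,62.078 L 239.129,72.464 A 118.000,118.000 0 0 0 238.768,72.139 Z" fill="#2b8cbe" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="gene-aggregates-agg-3-11" d="M 272.288,90.606 A 132.000,132.000 0 0 1 281.045,107.350 L 268.207,112.934 A 118.000,118.000 0 0 0 260.378,97.966 Z" fill="#2b8cbe" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="gene-aggregates-agg-4-12" d="M 291.797,152.685 A 132.000,132.000 0 0 1 287.185,195.327 L 273.696,191.580 A 118.000,118.000 0 0 0 277.819,153.461 Z" fill="#2b8cbe" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="gene-aggregates-agg-5-13" d="M 276.938,221.233 A 132.000,132.000 0 0 1 243.338,262.366 L 234.499,251.509 A 118.000,118.000 0 0 0 264.536,214.739 Z" fill="#2b8cbe" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="gene-aggregates-agg-6-14" d="M 221.614,276.738 A 132.000,132.000 0 0 1 182.124,290.133 L 179.778,276.331 A 118.000,118.000 0 0 0 215.079,264.357 Z" fill="#2b8cbe" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="gene-aggregates-agg-7-15" d="M 158.322,291.989 A 132.000,132.000 0 0 1 143.397,290.952 L 145.158,277.063 A 118.000,118.000 0 0 0 158.500,277.990 Z" fill="#2b8cbe" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="gene-aggregates-agg-8-16" d="M 118.813,285.410 A 132.000,132.000 0 0 1 111.316,282.694 L 116.479,269.681 A 118.000,118.000 0 0 0 123.181,272.109 Z" fill="#2b8cbe" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="gene-aggregates-agg-9-17" d="M 81.844,266.375 A 132.000,132.000 0 0 1 63.372,249.928 L 73.620,240.390 A 118.000,118.000 0 0 0 90.134,255.093 Z" fill="#2b8cbe" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="gene-aggregates-agg-10-18" d="M 38.176,210.823 A 132.000,132.000 0 0 1 34.047,199.495 L 47.406,195.306 A 118.000,118.000 0 0 0 51.097,205.433 Z" fill="#2b8cbe" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="gene-aggregates-agg-11-19" d="M 28.310,169.045 A 132.000,132.000 0 0 1 28.011,161.718 L 42.010,161.536 A 118.000,118.000 0 0 0 42.277,168.086 Z" fill="#2b8cbe" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="gene-aggregates-agg-12-20" d="M 33.268,123.080 A 132.000,132.000 0 0 1 52.088,83.981 L 63.533,92.043 A 118.000,118.000 0 0 0 46.710,126.995 Z" fill="#2b8cbe" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
    <path id="gene-aggregates-agg-13-21" d="M 75.954,58.214 A 132.000,132.000 0 0 1 124.058,32.987 L 127.870,46.458 A 118.000,118.000 0 0 0 84.868,69.010 Z" fill="#2b8cbe" stroke="none" stroke-width="0" opacity="1.000" fill-rule="evenodd"/>
  </g>
</svg>
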