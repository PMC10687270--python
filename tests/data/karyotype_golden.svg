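<svg xmlns="http://www.w3.org/2000/svg" width="146" height="420" viewBox="0 0 146 420">
<text x="20" y="16" font-size="12" font-family="sans-serif" class="title">B karyotype painted by A (left) and A (right)</text>
<rect x="20" y="40" width="12" height="320" fill="#f2f2f2" stroke="#555555" stroke-width="0.4" class="ideogram" data-chrom="B1" data-species="A"/>
<rect x="20" y="40" width="12" height="182.86" fill="#1f77b4" class="block" data-target="A1" data-species="A"/>
<rect x="20" y="222.86" width="12" height="79.56" fill="#aec7e8" class="block" data-target="A2" data-species="A"/>
<rect x="20" y="309.11" width="12" height="50.89" fill="#aec7e8" class="block" data-target="A2" data-species="A"/>
<rect x="35" y="40" width="12" height="320" fill="#f2f2f2" stroke="#555555" stroke-width="0.4" class="ideogram" data-chrom="B1" data-species="A"/>
<rect x="35" y="40" width="12" height="182.86" fill="#1f77b4" class="block" data-target="A1" data-species="A"/>
<rect x="35" y="222.86" width="12" height="79.56" fill="#aec7e8" class="block" data-target="A2" data-species="A"/>
<rect x="35" y="309.11" width="12" height="50.89" fill="#aec7e8" class="block" data-target="A2" data-species="A"/>
<circle cx="33.5" cy="146.67" r="3" fill="#000000" class="centromere" data-chrom="B1"/>
<text x="20" y="374" font-size="10" font-family="sans-serif" class="chrom-label">B1</text>
<rect x="73" y="40" width="12" height="106.67" fill="#f2f2f2" stroke="#555555" stroke-width="0.4" class="ideogram" data-chrom="B2" data-species="A"/>
<rect x="73" y="40" width="12" height="26.13" fill="#ff7f0e" class="block" data-target="A3" data-species="A"/>
<rect x="73" y="66.13" width="12" height="17.66" fill="#ff7f0e" class="block" data-target="A3" data-species="A"/>
<rect x="73" y="83.8" width="12" height="18.08" fill="#ff7f0e" class="block" data-target="A3" data-species="A"/>
<rect x="73" y="101.88" width="12" height="10.31" fill="#ff7f0e" class="block" data-target="A3" data-species="A"/>
<rect x="73" y="112.19" width="12" height="34.48" fill="#ff7f0e" class="block" data-target="A3" data-species="A"/>
<rect x="88" y="40" width="12" height="106.67" fill="#f2f2f2" stroke="#555555" stroke-width="0.4" class="ideogram" data-chrom="B2" data-species="A"/>
<rect x="88" y="40" width="12" height="26.13" fill="#ff7f0e" class="block" data-target="A3" data-species="A"/>
<rect x="88" y="66.13" width="12" height="17.66" fill="#ff7f0e" class="block" data-target="A3" data-species="A"/>
<rect x="88" y="83.8" width="12" height="18.08" fill="#ff7f0e" class="block" data-target="A3" data-species="A"/>
<rect x="88" y="101.88" width="12" height="10.31" fill="#ff7f0e" class="block" data-target="A3" data-species="A"/>
<rect x="88" y="112.19" width="12" height="34.48" fill="#ff7f0e" class="block" data-target="A3" data-species="A"/>
<circle cx="86.5" cy="75.56" r="3" fill="#000000" class="centromere" data-chrom="B2"/>
<text x="73" y="160.67" font-size="10" font-family="sans-serif" class="chrom-label">B2</text>
<rect x="20" y="400" width="76.19" height="3" fill="#000000" class="scale-bar"/>
<text x="102.19" y="404" font-size="10" font-family="sans-serif" class="scale-label">50 Mb</text>
</svg>
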