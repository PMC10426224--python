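>CAC00532 Hev b 9 enolase isoform 1|Hevea brasiliensis
MAITIVSVRARQIFDSRGNPTVEADVKLSDGYLARAAVPSGASTGIYEALELRDGGSDYL
GKGVSKAVENVNIIIGPALVGKDPTDQVGIDNFMVQQLDGTVNEWGWCKQKLGANAILAV
SLAVCKAGAHVKGIPLYEHIANLAGNKNLVLPVPAFNVINGGSHAGNKLAMQEFMILPVG
ASSFKEAMKMGAEVYHHLKSVIKKKYGQDATNVGDEGGFAPNIQENKEGLELLKTAIAKA
GYTGKVVIGMDVAASEFYGSDQTYDLNFKEENNNGSQKISGEALKDLYKSFVAEYPIVSI
EDPFDQDDWAHYAKLTSEIGEKVQIVGDDLLVTNPKRVEKAIKEKACNALLLKVNQIGSV
TESIEAVKMSKRAGWGVMASHRSGETEDTFIADLSVGLATGQIKTGAPCRSERLAKYNQL
LRIEEELGSEAVYAGANFRKPVEPY
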