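ccdc_id,molecule,phi1,phi2,phi3,phi4,c1c5_printed
1249410,ribitol,171,-62,-172,71,4.5
662559,ribitol,171,-61,-171,73,4.6
1015979,ribitol,171,-61,-170,73,4.6
1103512,d-arabitol,58,178,178,64,5.1
1287063,d-arabitol,173,174,176,66,5.1
2150172,d-arabitol,177,175,180,62,5.1
2076894,d-arabitol,64,176,171,56,5.1
1298203,xylitol,173,70,176,175,4.5
223330,xylitol,173,70,176,175,4.5
1015980,xylitol,173,70,176,175,4.5
1432562,xylitol,173,70,176,175,4.5
1423912,xylitol,173,70,176,175,4.5
2008303,xylitol,173,70,176,175,4.5
2021790,xylitol,173,70,177,175,4.5
2021791,xylitol,175,176,70,174,4.5
2021792,xylitol,176,176,69,175,4.4
2021793,xylitol,175,177,70,176,4.4
2021794,xylitol,175,176,70,174,4.4
2021795,xylitol,175,176,71,177,4.4
2021796,xylitol,175,174,69,179,4.4
2021798,xylitol,178,163,72,179,4.4
2021799,xylitol,175,175,69,177,4.4
2021800,xylitol,172,173,69,173,4.4
1898654,xylitol,175,176,70,173,4.5
2008299,xylitol,173,70,176,175,4.5
2008300,xylitol,173,70,176,175,4.5
2008301,xylitol,173,70,176,175,4.5
2008302,xylitol,173,70,176,175,4.5
2008304,xylitol,173,70,176,175,4.5
2008266,xylitol,173,70,176,175,4.5
2008270,xylitol,173,70,176,175,4.5
2008283,xylitol,173,70,176,175,4.5
2008280,xylitol,173,70,176,175,4.5
2060247,xylitol,173,70,176,175,4.5
2085455,xylitol,173,70,176,175,4.5
1987830,xylitol,173,70,176,175,4.5
1962229,xylitol,173,70,176,175,4.5
1962230,xylitol,173,70,176,175,4.5
1962231,xylitol,173,70,176,175,4.5
1962232,xylitol,173,70,176,175,4.5
1984051,xylitol,173,70,176,175,4.5
2081791,xylitol,173,70,176,175,4.5
2081792,xylitol,174,70,176,175,4.5
2081793,xylitol,174,70,176,175,4.5
2081794,xylitol,173,70,176,175,4.5
2076896,xylitol,175,176,70,173,4.5
2076897,xylitol,173,70,176,175,4.5
2008298,xylitol,173,70,176,175,4.5
2021797,xylitol,172,174,73,180,4.4
2081788,xylitol,173,70,176,175,4.5
2081789,xylitol,173,70,176,175,4.5
2081790,xylitol,173,70,176,175,4.5
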