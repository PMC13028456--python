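Base Points,"More than 2,000,000","1,000,000 to 2,000,000","500,000 to 1,000,000","300,000 to 500,000","100,000 to 300,000","50,000 to 100,000","30,000 to 50,000","10,000 to 30,000","5000 to 10,000",3000 to 5000,1000 to 3000,500 to 1000,100 to 500,10 to 100,1 to 10
50,104,260,260,273,585,1287,1560,6500,"10,920","11,050","31,070","37,310","70,070","66,560","183,430"
45,96,240,240,252,540,1188,1440,6000,"10,080","10,200","28,680","34,440","64,680","61,440","169,320"
40,88,220,220,231,495,1089,1320,5500,9240,9350,"26,290","31,570","59,290","56,320","155,210"
35,80,200,200,210,450,990,1200,5000,8400,8500,"23,900","28,700","53,900","51,200","141,100"
30,72,180,180,189,405,891,1080,4500,7560,7650,"21,510","25,830","48,510","46,080","126,990"
25,64,160,160,168,360,792,960,4000,6720,6800,"19,120","22,960","43,120","40,960","112,880"
20,56,140,140,147,315,693,840,3500,5880,5950,"16,730","20,090","37,730","35,840","98,770"
15,48,120,120,126,270,594,720,3000,5040,5100,"14,340","17,220","32,340","30,720","84,660"
10,40,100,100,105,225,495,600,2500,4200,4250,"11,950","14,350","26,950","25,600","70,550"
5,32,80,80,84,180,396,480,2000,3360,3400,9560,"11,480","21,560","20,480","56,440"
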